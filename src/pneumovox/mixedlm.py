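"""Weighted linear mixed model with a single random-intercept variance component.

The model is

    y_i = x_i' beta + u_{g(i)} + e_i,     u_g ~ N(0, sigma2_u),
    e_i ~ N(0, sigma2_e / w_i),

with independent random intercepts u_g for every level g of a grouping
factor (here: patient x dose-bin x density-bin cells) and known observation
weights w_i scaling the residual precision — the structure used when a
density-dependent random intercept is declared with a patient-by-dose
crossed subject.  Estimation is REML (or ML) by profiling: for a given
variance ratio lambda = sigma2_u / sigma2_e the GLS solution and the
profiled sigma2_e are closed-form via the Woodbury identity applied block
by block, so the criterion is minimized over the single scalar lambda.
This is deterministic given the data (no seeds involved).

Denominator degrees of freedom for t- and F-tests use the Satterthwaite
approximation (Fai–Cornelius for multi-row contrasts) computed from the
numeric REML information of (sigma2_u, sigma2_e).  When the variance
component is pinned at zero the residual degrees of freedom are used and
the fit is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = ["ConvergenceError", "RandomInterceptFit", "fit_random_intercept"]

_LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """REML/ML optimization failed; carries the evaluation trace."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


class _Profile:
    """Pre-computed sufficient statistics for profiled (RE)ML evaluations."""

    def __init__(self, X: np.ndarray, y: np.ndarray, w: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        self.X, self.y, self.w = X, y, w
        _, codes = np.unique(groups, return_inverse=True)
        self.G = int(codes.max()) + 1 if self.n else 0
        Z = sparse.csr_matrix((w, (codes, np.arange(self.n))), shape=(self.G, self.n))
        self.XtWX = X.T @ (X * w[:, None])
        self.XtWy = X.T @ (w * y)
        self.ytWy = float(w @ (y * y))
        self.T = np.asarray(Z @ X)          # group sums of w * x
        self.ty = np.asarray(Z @ y).ravel() # group sums of w * y
        self.s = np.asarray(Z @ np.ones(self.n)).ravel()  # group sums of w
        self.sumlogw = float(np.log(w).sum())
        self.codes = codes

    def gls(self, lam: float):
        """GLS pieces at variance ratio lam: beta, rss, log-dets, XtOX inverse factor."""
        c = lam / (1.0 + lam * self.s)
        XtOX = self.XtWX - (self.T * c[:, None]).T @ self.T
        XtOy = self.XtWy - self.T.T @ (c * self.ty)
        ytOy = self.ytWy - float(c @ (self.ty * self.ty))
        try:
            cho = cho_factor(XtOX)
        except np.linalg.LinAlgError:
            # near-deterministic data at extreme variance ratios: regularize
            XtOX = XtOX + np.eye(self.p) * (1e-10 * np.trace(XtOX) / self.p)
            cho = cho_factor(XtOX)
        beta = cho_solve(cho, XtOy)
        rss = max(ytOy - float(beta @ XtOy), 1e-300)
        logdet_omega = -self.sumlogw + float(np.log1p(lam * self.s).sum())
        logdet_xtox = 2.0 * float(np.log(np.diag(cho[0])).sum())
        return beta, rss, logdet_omega, logdet_xtox, cho

    def deviance(self, lam: float, reml: bool) -> float:
        _, rss, ld_o, ld_x, _ = self.gls(lam)
        if reml:
            df = self.n - self.p
            return df * np.log(rss / df) + ld_o + ld_x + df * (1.0 + _LOG2PI)
        return self.n * np.log(rss / self.n) + ld_o + self.n * (1.0 + _LOG2PI)

    def m2ll(self, sigma2_u: float, sigma2_e: float, reml: bool = True) -> float:
        """-2 log-likelihood at an arbitrary (unprofiled) variance point."""
        lam = sigma2_u / sigma2_e
        _, rss, ld_o, ld_x, _ = self.gls(lam)
        out = self.n * np.log(sigma2_e) + ld_o + rss / sigma2_e + self.n * _LOG2PI
        if reml:
            out += ld_x - self.p * np.log(sigma2_e) - self.p * _LOG2PI
        return out


@dataclass
class RandomInterceptFit:
    """Fitted weighted random-intercept model."""

    params: np.ndarray
    names: list[str]
    cov_params: np.ndarray
    sigma2_u: float
    sigma2_e: float
    loglik: float            # REML log-likelihood
    loglik_ml: float
    aic: float               # ML-based: -2 loglik_ml + 2 (p + n_variance_params)
    aic_reml: float          # REML criterion + 2 covariance parameters (SAS-style)
    n_obs: int
    n_groups: int
    df_resid: int
    boundary: bool           # sigma2_u pinned at 0
    converged: bool = True
    ddf_method: str = "satterthwaite"
    _profile: _Profile | None = field(default=None, repr=False)
    _theta_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def _cov_at(self, sigma2_u: float, sigma2_e: float) -> np.ndarray:
        pr = self._profile
        *_, cho = pr.gls(sigma2_u / sigma2_e)
        return sigma2_e * cho_solve(cho, np.eye(pr.p))

    def _theta_steps(self):
        h_u = max(self.sigma2_u, 1e-3 * self.sigma2_e) * 1e-3
        h_e = self.sigma2_e * 1e-3
        return h_u, h_e

    def _contrast_df(self, L: np.ndarray) -> np.ndarray:
        """Satterthwaite df for each row of a contrast matrix."""
        if self.boundary or self._theta_cov is None:
            return np.full(L.shape[0], float(self.df_resid))
        h_u, h_e = self._theta_steps()
        covs = {}
        for d, (du, de) in enumerate([(h_u, 0.0), (0.0, h_e)]):
            covs[d] = (
                self._cov_at(self.sigma2_u + du, self.sigma2_e + de),
                self._cov_at(max(self.sigma2_u - du, 0.0), self.sigma2_e - de),
                (self.sigma2_u + du) - max(self.sigma2_u - du, 0.0) if du else 2 * de,
            )
        out = np.empty(L.shape[0])
        for m, l in enumerate(L):
            v = float(l @ self.cov_params @ l)
            grad = np.array(
                [(l @ covs[d][0] @ l - l @ covs[d][1] @ l) / covs[d][2] for d in (0, 1)]
            )
            denom = float(grad @ self._theta_cov @ grad)
            out[m] = 2.0 * v * v / denom if denom > 0 else float(self.df_resid)
        return np.clip(out, 1.0, None)

    def t_test(self, index: int) -> tuple[float, float, float]:
        """(t, satterthwaite df, two-sided p) for a single coefficient."""
        t = self.params[index] / self.bse[index]
        df = float(self._contrast_df(np.eye(len(self.params))[[index]])[0])
        return float(t), df, float(2.0 * stats.t.sf(abs(t), df))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        p = len(self.params)
        dfs = self._contrast_df(np.eye(p))
        tcrit = stats.t.ppf(1 - alpha / 2, dfs)
        return np.column_stack([self.params - tcrit * self.bse, self.params + tcrit * self.bse])

    def wald_f(self, L: np.ndarray) -> dict:
        """Wald F-test of H0: L beta = 0 with Fai–Cornelius denominator df."""
        L = np.atleast_2d(np.asarray(L, dtype=float))
        r = L.shape[0]
        M = L @ self.cov_params @ L.T
        Lb = L @ self.params
        F = float(Lb @ np.linalg.solve(M, Lb)) / r
        # spectral decomposition -> independent single-df contrasts
        evals, evecs = np.linalg.eigh(M)
        keep = evals > max(evals.max(), 1e-300) * 1e-12
        Q = (evecs.T[keep]) @ L
        nus = self._contrast_df(Q)
        E = float(np.sum([nu / (nu - 2.0) for nu in nus if nu > 2.0]))
        ddf = 2.0 * E / (E - r) if E > r else float(self.df_resid)
        return {
            "F": F,
            "ndf": int(r),
            "ddf": float(ddf),
            "p": float(stats.f.sf(F, r, ddf)),
            "ddf_method": "residual" if self.boundary else "satterthwaite",
        }


def fit_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    reml: bool = True,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RandomInterceptFit:
    """Fit the weighted random-intercept model.

    Zero-weight observations are inert and removed before fitting; negative
    weights are an error.  ``groups`` may be any hashable labels; each
    distinct label receives an independent random intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative observation weights")
    keep = w > 0
    if not keep.any():
        raise ValueError("all observation weights are zero")
    X, y, w = X[keep], y[keep], w[keep]
    groups = np.asarray(groups)[keep]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few non-zero-weight observations ({n}) for {p} parameters")
    names = names or [f"x{j}" for j in range(p)]

    pr = _Profile(X, y, w, groups)
    trace: list[tuple[float, float]] = []

    def crit(u: float) -> float:
        val = pr.deviance(np.exp(u), reml=reml)
        trace.append((float(np.exp(u)), float(val)))
        return val

    res = optimize.minimize_scalar(
        crit, bounds=(-30.0, 12.0), method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise ConvergenceError(f"variance-ratio optimization failed: {res.message}", trace)
    lam = float(np.exp(res.x))
    dev0 = pr.deviance(0.0, reml=reml)
    boundary = dev0 <= res.fun + 1e-10 or res.x <= -30.0 + 1e-6
    if boundary:
        lam = 0.0
        warnings.warn("random-intercept variance pinned at 0 (singular fit)", stacklevel=2)

    beta, rss, *_ , cho = pr.gls(lam)
    df_resid = n - p
    sigma2_e = rss / df_resid if reml else rss / n
    sigma2_u = lam * sigma2_e
    cov = sigma2_e * cho_solve(cho, np.eye(p))
    ll_reml = -0.5 * pr.deviance(lam, reml=True)
    ll_ml = -0.5 * pr.deviance(lam, reml=False)
    n_vc = 1 if boundary else 2

    fit = RandomInterceptFit(
        params=beta,
        names=list(names),
        cov_params=cov,
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        loglik=float(ll_reml),
        loglik_ml=float(ll_ml),
        aic=float(-2.0 * ll_ml + 2.0 * (p + n_vc)),
        aic_reml=float(-2.0 * ll_reml + 2.0 * n_vc),
        n_obs=n,
        n_groups=pr.G,
        df_resid=df_resid,
        boundary=bool(boundary),
        _profile=pr,
    )
    if not boundary:
        fit._theta_cov = _theta_cov(pr, sigma2_u, sigma2_e)
        if fit._theta_cov is None:
            fit.boundary = True  # information not invertible; residual df fallback
            fit.ddf_method = "residual"
    else:
        fit.ddf_method = "residual"
    return fit


def _theta_cov(pr: _Profile, sigma2_u: float, sigma2_e: float) -> np.ndarray | None:
    """Asymptotic covariance of (sigma2_u, sigma2_e) from the numeric REML Hessian."""
    theta = np.array([sigma2_u, sigma2_e])
    h = np.array([max(sigma2_u, 1e-3 * sigma2_e), sigma2_e]) * 1e-4

    def f(t):
        return pr.m2ll(max(t[0], 1e-300), max(t[1], 1e-300), reml=True)

    H = np.empty((2, 2))
    f0 = f(theta)
    for i in range(2):
        ei = np.zeros(2); ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, 2):
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    info = H / 2.0
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or cov[0, 0] <= 0 or cov[1, 1] <= 0:
        return None
    return cov
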