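"""Separating high-grade from low-grade pneumonitis by dose-binned infiltrate load.

Tools: Ward minimum-variance hierarchical clustering of the per-patient
11-vectors of infiltrate load per 5 Gy dose bin, single-feature logistic
ROC/AUC per dose bin with a Bonferroni-style significance level, the
">15% infiltrate below 5 Gy" rule, and nonparametric group comparisons of
dosimetric metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import roc_auc_score

from .volumetry import DoseBinFeatures

__all__ = [
    "ClusterTree",
    "RocReport",
    "cluster_cohort",
    "roc_per_dose_bin",
    "delong_auc_ci",
    "low_dose_rule",
    "threshold_sweep",
    "group_compare",
    "kruskal_across_bins",
]

HIGH_GRADE_THRESHOLD = 3      # CTCAE grade >= 3 counts as high-grade
ALPHA_BONFERRONI = 0.002      # multiplicity-adjusted level for per-bin AUCs
LOW_DOSE_RULE_THRESHOLD = 0.15


def _labels_from(features: DoseBinFeatures, labels=None) -> np.ndarray:
    if labels is not None:
        return np.asarray(labels).astype(int)
    return np.array(
        [int(features.grades[p] >= HIGH_GRADE_THRESHOLD) for p in features.patients]
    )


def _feature_matrix(features: DoseBinFeatures) -> tuple[np.ndarray, bool]:
    X = features.values.to_numpy(dtype=float)
    had_missing = bool(np.isnan(X).any())
    return np.nan_to_num(X, nan=0.0), had_missing


@dataclass
class ClusterTree:
    """Ward linkage over patients with grade labels and a purity summary."""

    linkage: np.ndarray
    patients: list[str]
    leaf_order: list[str]
    labels: np.ndarray
    newick: str
    bipartition_purity: float     # max-class purity of the 2-cluster cut
    bipartition_pure: bool
    preprocessing: str
    imputed_missing: bool = False

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _to_newick(Z: np.ndarray, names: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cluster_cohort(features: DoseBinFeatures, preprocessing: str = "standardize") -> ClusterTree:
    """Ward hierarchical clustering of per-dose-bin infiltrate loads.

    ``preprocessing`` is 'standardize' (per-feature z-scores, default),
    'whiten' (PCA whitening) or 'none'.  Missing bins are imputed as 0 with
    a flag.  Constant feature sets are an error (no clustering structure).
    """
    if len(features.patients) < 2:
        raise ValueError("clustering requires at least 2 patients")
    X, imputed = _feature_matrix(features)
    if np.allclose(X, X[0]):
        raise ValueError("constant features: all patients identical")
    sd = X.std(axis=0, ddof=0)
    if preprocessing == "standardize":
        keep = sd > 0
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    elif preprocessing == "whiten":
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        keep = s > s.max() * 1e-10
        X = U[:, keep] * np.sqrt(max(len(X) - 1, 1))
    elif preprocessing != "none":
        raise ValueError(f"unknown preprocessing {preprocessing!r}")

    Z = hierarchy.ward(X)
    labels = _labels_from(features)
    order = hierarchy.leaves_list(Z)
    cut = hierarchy.fcluster(Z, 2, criterion="maxclust")
    purity = 0.0
    for k in np.unique(cut):
        members = labels[cut == k]
        purity += max((members == 0).sum(), (members == 1).sum())
    purity /= len(labels)
    pure = all(len(np.unique(labels[cut == k])) == 1 for k in np.unique(cut))
    return ClusterTree(
        linkage=Z,
        patients=list(features.patients),
        leaf_order=[features.patients[i] for i in order],
        labels=labels,
        newick=_to_newick(Z, list(features.patients)),
        bipartition_purity=float(purity),
        bipartition_pure=bool(pure),
        preprocessing=preprocessing,
        imputed_missing=imputed,
    )


def delong_auc_ci(x: np.ndarray, y01: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong covariance confidence interval.

    Returns (auc, lo, hi) for the orientation given by the data (larger x in
    class 1 gives AUC > 0.5).  Degenerate variance (e.g. perfect separation)
    collapses the interval onto the point estimate.
    """
    x = np.asarray(x, dtype=float)
    y01 = np.asarray(y01).astype(int)
    pos, neg = x[y01 == 1], x[y01 == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # placement values (midrank handling of ties)
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / n for p in pos])
    v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / m for q in neg])
    auc = float(v10.mean())
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n if m > 1 and n > 1 else 0.0
    if var <= 0:
        return auc, auc, auc
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def _logistic_lr(x: np.ndarray, y01: np.ndarray) -> tuple[float, float, bool]:
    """Likelihood-ratio p of a single-feature logistic model vs. the null.

    Under complete separation the supremum log-likelihood of the full model
    is 0, the LR statistic equals -2 * ll_null, and the coefficient is
    flagged non-finite.
    """
    n = len(y01)
    k = int(y01.sum())
    ll_null = k * np.log(k / n) + (n - k) * np.log((n - k) / n)
    pos, neg = x[y01 == 1], x[y01 == 0]
    separated = pos.min() > neg.max() or pos.max() < neg.min()
    if separated:
        lr = -2.0 * ll_null
        return float(stats.chi2.sf(lr, 1)), float("inf"), False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y01, sm.add_constant(x)).fit(disp=0, maxiter=200)
            coef = float(res.params[1])
            lr = 2.0 * (res.llf - ll_null)
            finite = bool(np.isfinite(coef)) and not getattr(res, "mle_retvals", {}).get(
                "converged", True
            ) is False
            return float(stats.chi2.sf(max(lr, 0.0), 1)), coef, finite
        except Exception:
            lr = -2.0 * ll_null
            return float(stats.chi2.sf(lr, 1)), float("nan"), False


@dataclass
class RocReport:
    """Per-dose-bin single-feature discrimination of high- vs low-grade."""

    per_bin: pd.DataFrame
    alpha: float = ALPHA_BONFERRONI
    min_high_grade_low_dose_pv: float = float("nan")
    notes: dict = field(default_factory=dict)


def roc_per_dose_bin(features: DoseBinFeatures, labels=None) -> RocReport:
    """ROC/AUC of each 5 Gy dose-bin infiltrate load for grade >= 3 vs <= 2.

    AUC is the rank (Mann–Whitney) statistic via a logistic-score-free ROC;
    the p-value is the likelihood-ratio test of the single-feature logistic
    model.  AUCs are reported oriented >= 0.5 with the orientation flagged;
    confidence intervals use the DeLong method.  Complete separation keeps
    the AUC and rank CI and flags the logistic coefficient as non-finite.
    """
    y = _labels_from(features, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both grade classes must be present")
    X, imputed = _feature_matrix(features)
    rows = []
    for b in range(X.shape[1]):
        x = X[:, b]
        auc_raw = float(roc_auc_score(y, x))
        flipped = auc_raw < 0.5
        auc, lo, hi = delong_auc_ci(-x if flipped else x, y)
        p, coef, finite = _logistic_lr(x, y)
        rows.append(
            {
                "dose_bin": b,
                "auc": auc,
                "ci_low": lo,
                "ci_high": hi,
                "lr_p": p,
                "logit_coef": coef,
                "coef_finite": finite,
                "orientation_flipped": flipped,
                "significant": p < ALPHA_BONFERRONI,
            }
        )
    per_bin = pd.DataFrame(rows).set_index("dose_bin")
    high = X[y == 1, 0]
    return RocReport(
        per_bin=per_bin,
        min_high_grade_low_dose_pv=float(high.min()),
        notes={"imputed_missing": imputed, "ci_method": "delong"},
    )


def low_dose_rule(
    features: DoseBinFeatures, labels=None, threshold: float = LOW_DOSE_RULE_THRESHOLD
) -> dict:
    """Check that every high-grade patient has > threshold infiltrate below 5 Gy."""
    y = _labels_from(features, labels)
    X, _ = _feature_matrix(features)
    pids = np.array(features.patients)
    high = y == 1
    passes = X[:, 0] > threshold
    violators = [str(p) for p in pids[high & ~passes]]
    return {
        "threshold": threshold,
        "n_high_grade": int(high.sum()),
        "all_pass": len(violators) == 0,
        "violators": violators,
        "min_high_grade_pv": float(X[high, 0].min()) if high.any() else float("nan"),
    }


def threshold_sweep(features: DoseBinFeatures, labels=None, bin_index: int = 0) -> pd.DataFrame:
    """Sensitivity/specificity of the '> t in a dose bin' rule over thresholds."""
    y = _labels_from(features, labels)
    X, _ = _feature_matrix(features)
    x = X[:, bin_index]
    rows = []
    for t in np.unique(np.concatenate([[0.0], x])):
        pred = x > t
        tp = int((pred & (y == 1)).sum()); fn = int((~pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum()); fp = int((pred & (y == 0)).sum())
        rows.append(
            {
                "threshold": float(t),
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def group_compare(values, labels, paired: bool = False) -> dict:
    """Rank test of a metric between grade groups.

    Unpaired rank-sum (Mann–Whitney) by default; ``paired=True`` forces the
    Wilcoxon signed-rank test on matched samples.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    a, b = values[labels == 1], values[labels == 0]
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal group sizes")
        if np.allclose(a, b):
            return {"test": "signed-rank", "statistic": 0.0, "p": 1.0}
        res = stats.wilcoxon(a, b)
        return {"test": "signed-rank", "statistic": float(res.statistic), "p": float(res.pvalue)}
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "rank-sum", "statistic": float(res.statistic), "p": float(res.pvalue)}


def kruskal_across_bins(matrix) -> dict:
    """Kruskal–Wallis test across dose bins (columns) of a patients x bins table."""
    M = np.asarray(matrix, dtype=float)
    cols = [c[~np.isnan(c)] for c in M.T]
    cols = [c for c in cols if len(c) > 0]
    if len(cols) < 2:
        raise ValueError("need at least 2 non-empty bins")
    flat = np.concatenate(cols)
    if np.allclose(flat, flat[0]):
        return {"statistic": 0.0, "p": 1.0, "df": len(cols) - 1}
    H, p = stats.kruskal(*cols)
    return {"statistic": float(H), "p": float(p), "df": len(cols) - 1}
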