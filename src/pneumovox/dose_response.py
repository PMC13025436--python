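"""Weighted mixed-model analysis of partial infiltrate volumes.

Fixed effects are classification effects for the 5 Gy dose bin (or a
continuous linear / linear-quadratic dose term) and the 50 HU density bin;
the random structure is a density-dependent random intercept with the
crossed patient-by-dose-bin combination as subject — i.e. one independent
random intercept per (patient, dose bin, density bin) cell with a single
shared variance component.  Observations are the partial infiltrate volumes
per 0.1 Gy dose step and density bin, weighted by the lung volume each cell
represents.  Reference-cell coding uses the [0,5) Gy and [-1000,-950) HU
levels as references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import RandomInterceptFit, fit_random_intercept
from .volumetry import ObservationTable

__all__ = [
    "ModelSpec",
    "MixedFit",
    "fit_mixed",
    "test_interaction",
    "compare_dose_forms",
    "leave_one_patient_out",
    "fit_per_patient",
    "normal_scores_refit",
    "density_distribution_test",
    "patient_hu_volumes",
    "subset_patients",
]

DOSE_FORMS = ("step", "linear", "linear_quadratic", "constant")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect dose form + shared random structure and weighting."""

    dose_form: str = "step"
    interaction: bool = False
    reml: bool = True

    def __post_init__(self) -> None:
        if self.dose_form not in DOSE_FORMS:
            raise ValueError(f"dose_form must be one of {DOSE_FORMS}")
        if self.interaction and self.dose_form != "step":
            raise ValueError("the dose x density interaction requires the step dose form")


def _design(table: ObservationTable, spec: ModelSpec):
    """Design matrix, response, weights and random-effect grouping."""
    df = table.data
    scheme = table.scheme
    n_bins, n_hu = scheme.n_dose_bins, scheme.n_hu_bins
    y = df["pv"].to_numpy(dtype=float)
    w = df["weight"].to_numpy(dtype=float)
    dose_bin = df["dose_bin"].to_numpy()
    hu_bin = df["hu_bin"].to_numpy()
    pid_codes, _ = pd.factorize(df["patient_id"], sort=True)
    groups = (pid_codes * n_bins + dose_bin) * n_hu + hu_bin

    cols = [np.ones(len(df))]
    names = ["intercept"]
    hu_dummies = []
    for h in range(1, n_hu):
        col = (hu_bin == h).astype(float)
        hu_dummies.append(col)
        cols.append(col)
        names.append(f"hu[{h}]")
    dose_dummies = []
    if spec.dose_form == "step":
        for d in range(1, n_bins):
            col = (dose_bin == d).astype(float)
            dose_dummies.append(col)
            cols.append(col)
            names.append(f"dose[{d}]")
    elif spec.dose_form in ("linear", "linear_quadratic"):
        x = scheme.dose_step_midpoints()[df["dose_step"].to_numpy()]
        cols.append(x)
        names.append("dose_gy")
        if spec.dose_form == "linear_quadratic":
            cols.append(x * x)
            names.append("dose_gy2")
    if spec.interaction:
        for d, dcol in enumerate(dose_dummies, start=1):
            for h, hcol in enumerate(hu_dummies, start=1):
                cols.append(dcol * hcol)
                names.append(f"dose[{d}]:hu[{h}]")
    X = np.column_stack(cols)
    return X, names, y, w, groups


@dataclass
class MixedFit:
    """Fixed dose/density profiles, variance components and test battery."""

    spec: ModelSpec
    engine: RandomInterceptFit
    scheme_bins: tuple[int, int]          # (n dose bins, n HU bins)
    alpha: np.ndarray                     # dose fixed effects incl. reference 0
    alpha_se: np.ndarray
    alpha_ci: np.ndarray                  # (n dose bins, 2)
    beta: np.ndarray                      # density fixed effects incl. reference 0
    beta_se: np.ndarray
    beta_ci: np.ndarray
    intercept: float
    sigma2_u: float
    sigma2_e: float
    tests: dict = field(default_factory=dict)
    slope: float | None = None            # linear forms only
    slope_se: float | None = None
    slope_p: float | None = None

    @property
    def aic(self) -> float:
        return self.engine.aic

    @property
    def aic_reml(self) -> float:
        return self.engine.aic_reml

    @property
    def monotone_alpha(self) -> bool:
        """Whether the fitted dose profile is non-decreasing over the bins."""
        return bool(np.all(np.diff(self.alpha) >= 0))

    def coef_frame(self) -> pd.DataFrame:
        eng = self.engine
        return pd.DataFrame(
            {"coef": eng.params, "se": eng.bse}, index=eng.names
        )


def _collect_fit(table: ObservationTable, spec: ModelSpec, eng: RandomInterceptFit) -> MixedFit:
    n_bins, n_hu = table.scheme.n_dose_bins, table.scheme.n_hu_bins
    names = eng.names
    ci = eng.conf_int()

    def block(prefix, n_levels):
        vals = np.zeros(n_levels)
        ses = np.zeros(n_levels)
        cis = np.zeros((n_levels, 2))
        for lvl in range(1, n_levels):
            j = names.index(f"{prefix}[{lvl}]")
            vals[lvl] = eng.params[j]
            ses[lvl] = eng.bse[j]
            cis[lvl] = ci[j]
        return vals, ses, cis

    beta, beta_se, beta_ci = block("hu", n_hu)
    if spec.dose_form == "step":
        alpha, alpha_se, alpha_ci = block("dose", n_bins)
    else:
        alpha = np.zeros(n_bins); alpha_se = np.zeros(n_bins); alpha_ci = np.zeros((n_bins, 2))
    fit = MixedFit(
        spec=spec,
        engine=eng,
        scheme_bins=(n_bins, n_hu),
        alpha=alpha, alpha_se=alpha_se, alpha_ci=alpha_ci,
        beta=beta, beta_se=beta_se, beta_ci=beta_ci,
        intercept=float(eng.params[names.index("intercept")]),
        sigma2_u=eng.sigma2_u,
        sigma2_e=eng.sigma2_e,
    )
    if spec.dose_form in ("linear", "linear_quadratic"):
        j = names.index("dose_gy")
        t, dfree, pval = eng.t_test(j)
        fit.slope = float(eng.params[j])
        fit.slope_se = float(eng.bse[j])
        fit.slope_p = pval
    return fit


def _block_contrast(names: list[str], prefix: str) -> np.ndarray:
    rows = [j for j, nm in enumerate(names) if nm.startswith(prefix)]
    L = np.zeros((len(rows), len(names)))
    for r, j in enumerate(rows):
        L[r, j] = 1.0
    return L


def fit_mixed(table: ObservationTable, spec: ModelSpec | None = None) -> MixedFit:
    """Fit the weighted mixed model and run F-tests of the fixed effects.

    Requires at least two patients; zero-weight rows are inert.  F-tests for
    the dose and density classification effects are reported with
    Satterthwaite denominator degrees of freedom.
    """
    spec = spec or ModelSpec()
    if len(table.patients) < 2:
        raise ValueError("the cohort mixed model requires at least 2 patients")
    X, names, y, w, groups = _design(table, spec)
    eng = fit_random_intercept(X, y, w, groups, names=names, reml=spec.reml)
    fit = _collect_fit(table, spec, eng)
    if spec.dose_form == "step":
        L = _block_contrast(names, "dose[")
        if len(L):  # a single-dose-bin scheme has no dose contrast (constant model)
            fit.tests["dose"] = eng.wald_f(L)
    elif spec.dose_form in ("linear", "linear_quadratic"):
        fit.tests["dose"] = eng.wald_f(_block_contrast(names, "dose_gy"))
    fit.tests["density"] = eng.wald_f(
        _block_contrast(names, "hu[")[: table.scheme.n_hu_bins - 1]
    )
    if spec.interaction:
        fit.tests["interaction"] = eng.wald_f(_block_contrast(names, "dose[") [
            table.scheme.n_dose_bins - 1:
        ])
    return fit


def test_interaction(table: ObservationTable, spec: ModelSpec | None = None) -> dict:
    """F-test of the dose-bin x density-bin fixed interaction (step form)."""
    base = spec or ModelSpec()
    if base.dose_form != "step":
        raise ValueError("interaction test requires the step dose form")
    if len(table.patients) < 2:
        raise ValueError("the interaction test requires at least 2 patients")
    spec_i = ModelSpec(dose_form="step", interaction=True, reml=base.reml)
    X, names, y, w, groups = _design(table, spec_i)
    eng = fit_random_intercept(X, y, w, groups, names=names, reml=spec_i.reml)
    rows = [j for j, nm in enumerate(names) if ":hu[" in nm]
    L = np.zeros((len(rows), len(names)))
    for r, j in enumerate(rows):
        L[r, j] = 1.0
    return eng.wald_f(L)


def compare_dose_forms(table: ObservationTable) -> pd.DataFrame:
    """AIC table over the step / linear / linear-quadratic / constant forms.

    All forms share the data and random structure.  The AIC column comes from
    ML fits (fixed-effect structures differ, so REML criteria are not
    comparable); REML-based AICs are reported alongside.  Wald tests of the
    linear and quadratic coefficients accompany the continuous forms.
    """
    rows = []
    for form in DOSE_FORMS:
        spec_ml = ModelSpec(dose_form=form, reml=False)
        X, names, y, w, groups = _design(table, spec_ml)
        eng_ml = fit_random_intercept(X, y, w, groups, names=names, reml=False)
        eng_reml = fit_random_intercept(X, y, w, groups, names=names, reml=True)
        row = {
            "form": form,
            "aic": eng_ml.aic,
            "aic_reml": eng_reml.aic_reml,
            "loglik_ml": eng_ml.loglik_ml,
            "n_fixed": len(names),
        }
        for term in ("dose_gy", "dose_gy2"):
            if term in names:
                t, dfree, p = eng_reml.t_test(names.index(term))
                row[f"{term}_coef"] = eng_reml.params[names.index(term)]
                row[f"{term}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("form")


def subset_patients(table: ObservationTable, patients: list[str]) -> ObservationTable:
    keep = set(patients)
    missing = keep - set(table.patients)
    if missing:
        raise KeyError(f"unknown patients {sorted(missing)}")
    return ObservationTable(
        data=table.data[table.data["patient_id"].isin(keep)].reset_index(drop=True),
        scheme=table.scheme,
        lung_volume_ml={p: table.lung_volume_ml[p] for p in patients},
        step_lung_volume_ml={p: table.step_lung_volume_ml[p] for p in patients},
        grades={p: table.grades[p] for p in patients},
        qc={p: table.qc[p] for p in patients if p in table.qc},
    )


def leave_one_patient_out(table: ObservationTable, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Refit without each patient in turn; dose F-test p and monotonicity flag."""
    spec = spec or ModelSpec()
    patients = table.patients
    if len(patients) < 3:
        raise ValueError("leave-one-out requires at least 3 patients (refits need >= 2)")
    rows = []
    for left_out in patients:
        sub = subset_patients(table, [p for p in patients if p != left_out])
        fit = fit_mixed(sub, spec)
        rows.append(
            {
                "left_out": left_out,
                "dose_F": fit.tests["dose"]["F"],
                "dose_p": fit.tests["dose"]["p"],
                "monotone": fit.monotone_alpha,
            }
        )
    return pd.DataFrame(rows).set_index("left_out")


def fit_per_patient(table: ObservationTable) -> pd.DataFrame:
    """Per-patient linear dose slope (pv per density bin per Gy) with SE and p."""
    rows = []
    spec = ModelSpec(dose_form="linear")
    for pid in table.patients:
        sub = subset_patients(table, [pid])
        X, names, y, w, groups = _design(sub, spec)
        eng = fit_random_intercept(X, y, w, groups, names=names, reml=True)
        j = names.index("dose_gy")
        t, dfree, p = eng.t_test(j)
        rows.append(
            {"patient_id": pid, "slope": eng.params[j], "se": eng.bse[j], "t": t, "p": p}
        )
    return pd.DataFrame(rows).set_index("patient_id")


def blom_normal_scores(values: np.ndarray) -> np.ndarray:
    """Blom rank-based normal scores (average ranks for ties, constant 3/8)."""
    r = stats.rankdata(values, method="average")
    n = len(values)
    return stats.norm.ppf((r - 0.375) / (n + 0.25))


def normal_scores_refit(table: ObservationTable, spec: ModelSpec | None = None) -> MixedFit:
    """Refit after replacing pv by within-patient Blom normal scores.

    Scores are computed per patient over all non-zero-weight (dose step,
    density bin) cells, so the refit is invariant under any strictly
    monotone transform of the endpoint.
    """
    spec = spec or ModelSpec()
    data = table.data.copy()
    pv = data["pv"].to_numpy(dtype=float).copy()
    w = data["weight"].to_numpy(dtype=float)
    for pid in table.patients:
        sel = ((data["patient_id"] == pid) & (w > 0)).to_numpy()
        if sel.any():
            pv[sel] = blom_normal_scores(pv[sel])
    data["pv"] = pv
    scored = ObservationTable(
        data=data,
        scheme=table.scheme,
        lung_volume_ml=table.lung_volume_ml,
        step_lung_volume_ml=table.step_lung_volume_ml,
        grades=table.grades,
        qc=table.qc,
    )
    return fit_mixed(scored, spec)


def patient_hu_volumes(table: ObservationTable) -> pd.DataFrame:
    """Patients x density-bin matrix of infiltrate volume (mL)."""
    n_hu = table.scheme.n_hu_bins
    rows = {}
    for pid in table.patients:
        sub = table.data[table.data["patient_id"] == pid].sort_values(["dose_step", "hu_bin"])
        step_lung = table.step_lung_volume_ml[pid]
        inf_vol = sub["pv"].to_numpy() * step_lung[sub["dose_step"].to_numpy()]
        rows[pid] = inf_vol.reshape(-1, n_hu).sum(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(n_hu))


def density_distribution_test(counts, scores: np.ndarray | None = None) -> dict:
    """Row-mean-scores Cochran–Mantel–Haenszel test on a patients x bins table.

    Tests whether the location of the density distribution differs between
    patients.  ``counts`` holds per-patient frequencies (volumes or voxel
    counts) per density bin; ``scores`` are column (table) scores, defaulting
    to the bin index.  The statistic is invariant under affine score changes
    and is referred to chi-square with (patients - 1) degrees of freedom.
    """
    M = np.asarray(counts, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    if np.any(M < 0):
        raise ValueError("negative cell frequencies")
    a = np.arange(M.shape[1], dtype=float) if scores is None else np.asarray(scores, dtype=float)
    N = M.sum()
    if N <= 1:
        raise ValueError("table total must exceed 1")
    n_i = M.sum(axis=1)
    n_j = M.sum(axis=0)
    mu = float(a @ n_j) / N
    va = float(((a - mu) ** 2) @ n_j) / N
    S = M @ a
    U = (S - n_i * mu)[:-1]
    r = M.shape[0]
    V = va / (N - 1.0) * (N * np.diag(n_i[:-1]) - np.outer(n_i[:-1], n_i[:-1]))
    if va <= 0:
        return {"statistic": 0.0, "df": r - 1, "p": 1.0}
    stat = float(U @ np.linalg.solve(V, U))
    return {"statistic": stat, "df": r - 1, "p": float(stats.chi2.sf(stat, r - 1))}
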