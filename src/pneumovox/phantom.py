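"""Synthetic thoracic phantoms with a known dose/density infiltrate structure.

Each phantom patient has two ellipsoidal half-lungs, a spherical planning
target volume (PTV), a conformal-style dose field (prescription dose inside
the PTV, smooth sigmoidal falloff with distance from the PTV surface) and a
pulmonary infiltrate built from two components with known ground truth:

* a *dose-independent* component: a spatially correlated blob field
  (thresholded smoothed Gaussian noise) occupying a target fraction f of the
  lung outside the PTV.  The threshold is taken per 5 Gy dose bin so the
  realized fraction is exactly flat across dose bins — the defining property
  of a dose-independent process — while the patchy spatial structure is kept
  within bins.
* a *dose-driven* component: voxels sampled independently among the
  remaining lung with probability 22 * p[d] in dose bin d, where p is the
  per-density-bin dose-effect profile.  The realized infiltrate probability
  in bin d is therefore f + (1 - f) * 22 * p[d].

Infiltrated voxels are re-assigned CT densities: blob voxels draw their
50 HU bin from a unimodal density profile (default Gaussian peaking near
-500 HU), dose-driven voxels draw uniformly over the density range, so the
expected partial infiltrate volume per (dose bin, HU bin) cell is exactly
additive — no dose-density interaction.  Patient-level random effects
perturb the density-bin mixing weights per (dose bin, HU bin) cell with
independent log-normal factors, matching the crossed random-intercept
structure the downstream model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import ImageGrid, PatientCase

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "gaussian_density_profile",
    "default_high_grade_params",
    "default_low_grade_params",
    "generate_patient",
    "generate_cohort",
]

N_DOSE_BINS = 11
N_HU_BINS = 22
HU_RANGE = (-1000.0, 100.0)
HU_BIN_WIDTH = 50.0
DOSE_BIN_WIDTH = 5.0

#: [0-5) Gy-bin infiltrate fractions reported for high-grade pneumonitis
HIGH_GRADE_LOW_DOSE_RANGE = (0.179, 0.584)
#: strictly below the high-grade range, for the low-grade comparison cohort
LOW_GRADE_LOW_DOSE_RANGE = (0.02, 0.12)


def gaussian_density_profile(peak_hu: float = -500.0, width_hu: float = 150.0) -> np.ndarray:
    """Unnormalized unimodal weights over the 22 half-open 50 HU bins."""
    mids = HU_RANGE[0] + (np.arange(N_HU_BINS) + 0.5) * HU_BIN_WIDTH
    return np.exp(-0.5 * ((mids - peak_hu) / width_hu) ** 2)


@dataclass
class PhantomParams:
    """Full parameterization of one phantom patient (defaults: see module docs)."""

    grid_dims: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    # two half-lungs: (center mm, semi-axes mm)
    lung_ellipsoids: tuple = (
        ((130.0, 192.0, 96.0), (62.0, 105.0, 78.0)),
        ((254.0, 192.0, 96.0), (62.0, 105.0, 78.0)),
    )
    ptv_center: tuple[float, float, float] = (192.0, 192.0, 96.0)
    ptv_radius: float = 27.0
    prescribed_dose: float = 60.0
    dose_falloff_scale: float = 36.0
    dose_falloff_shape: float = 1.5
    baseline_lung_hu_mean: float = -850.0
    baseline_lung_hu_sd: float = 40.0
    # per-density-bin infiltrate probability increment per 5 Gy dose bin
    dose_effect_profile: np.ndarray = field(
        default_factory=lambda: 0.015 * np.arange(N_DOSE_BINS) / (N_DOSE_BINS - 1)
    )
    density_profile: np.ndarray = field(default_factory=gaussian_density_profile)
    dose_independent_fraction: float = 0.35
    random_effect_sd: float = 0.2
    blob_correlation_length: float = 12.0
    seed: int = 0
    # stratified (exact-allocation) sampling: blob fraction, dose-driven counts
    # and HU bin counts are fixed at their expectations per 0.1 Gy dose step
    # (largest-remainder rounding).  Used by oracle/recovery experiments where
    # the phantom must realize its generative expectations as sharply as
    # possible; the natural per-voxel sampling (default) is the study condition.
    stratified_sampling: bool = False
    # optional HU shift of the dose-driven density per dose-bin index; nonzero
    # values create a genuine dose x density interaction (power studies)
    dose_hu_shift_per_bin: float = 0.0
    # cohort-level per-patient draws (used by generate_cohort only)
    dose_independent_fraction_range: tuple[float, float] | None = None
    density_peak_range: tuple[float, float] | None = None
    density_peak_width: float = 150.0

    def __post_init__(self) -> None:
        self.dose_effect_profile = np.asarray(self.dose_effect_profile, dtype=float)
        self.density_profile = np.asarray(self.density_profile, dtype=float)
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")
        if self.dose_effect_profile.shape != (N_DOSE_BINS,):
            raise ValueError(f"dose_effect_profile must have {N_DOSE_BINS} entries")
        if np.any(self.dose_effect_profile < 0):
            raise ValueError("dose_effect_profile must be non-negative")
        if self.density_profile.shape != (N_HU_BINS,):
            raise ValueError(f"density_profile must have {N_HU_BINS} entries")
        if np.any(self.density_profile < 0) or self.density_profile.sum() <= 0:
            raise ValueError("density_profile must be non-negative with positive sum")
        if not 0.0 <= self.dose_independent_fraction < 1.0:
            raise ValueError("dose_independent_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Realized generative quantities for one phantom patient."""

    patient_id: str
    dose_independent_fraction: float
    true_dose_effect_profile: np.ndarray      # per-density-bin increments p[d]
    true_density_profile: np.ndarray          # normalized blob density mix
    true_attributable_fraction: float         # expected, in [0, 1]
    true_total_infiltrate_fraction: float     # expected, in [0, 1]
    realized_infiltrate_fraction: float
    random_effects: np.ndarray                # (11, 22) log-normal factors
    lung_bin_volume_ml: np.ndarray            # lung-outside-PTV volume per dose bin

    def true_alpha(self) -> np.ndarray:
        """Per-stratum fixed dose effects relative to the [0,5) Gy bin."""
        p = self.true_dose_effect_profile
        return (1.0 - self.dose_independent_fraction) * (p - p[0])

    def true_beta(self) -> np.ndarray:
        """Per-cell fixed density effects relative to the lowest HU bin."""
        pi = self.true_density_profile
        return self.dose_independent_fraction * (pi - pi[0])


def default_high_grade_params(seed: int = 0) -> PhantomParams:
    return PhantomParams(
        seed=seed,
        dose_independent_fraction_range=HIGH_GRADE_LOW_DOSE_RANGE,
        density_peak_range=(-600.0, -400.0),
    )

def default_low_grade_params(seed: int = 0) -> PhantomParams:
    return PhantomParams(
        seed=seed,
        dose_independent_fraction=0.07,
        dose_independent_fraction_range=LOW_GRADE_LOW_DOSE_RANGE,
        density_peak_range=(-600.0, -400.0),
    )


def _voxel_centers(params: PhantomParams):
    coords = [
        (np.arange(n) + 0.5) * s
        for n, s in zip(params.grid_dims, params.spacing)
    ]
    return np.meshgrid(*coords, indexing="ij")


def _lung_and_ptv_masks(params: PhantomParams):
    xx, yy, zz = _voxel_centers(params)
    lungs = np.zeros(params.grid_dims, dtype=bool)
    for center, semi in params.lung_ellipsoids:
        lungs |= (
            ((xx - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((zz - center[2]) / semi[2]) ** 2
        ) <= 1.0
    c, r = params.ptv_center, params.ptv_radius
    dist2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
    ptv = dist2 <= r * r
    dist_to_ptv = np.maximum(np.sqrt(dist2) - r, 0.0)
    return lungs, ptv, dist_to_ptv


def _check_ptv_in_lung_region(params: PhantomParams, lungs: np.ndarray) -> None:
    xx, yy, zz = _voxel_centers(params)
    c, r = params.ptv_center, params.ptv_radius
    for axis, (grid, ci) in enumerate(zip((xx, yy, zz), c)):
        vals = grid[lungs]
        if ci - r < vals.min() - 1e-9 or ci + r > vals.max() + 1e-9:
            raise ValueError(
                f"PTV (center {c}, radius {r}) extends outside the lung bounding region on axis {axis}"
            )


def _dose_field(params: PhantomParams, dist_to_ptv: np.ndarray) -> np.ndarray:
    """Prescription dose inside the PTV, sigmoidal falloff with distance outside.

    The falloff is D(r) = D_presc * 2 / (1 + exp((r/s)^k)): continuous at the
    PTV surface, with a conformal shoulder (shape exponent k) and a smooth
    tail spanning the full dose range down to ~0 Gy in the far lung.
    """
    s, k = params.dose_falloff_scale, params.dose_falloff_shape
    return params.prescribed_dose * 2.0 / (1.0 + np.exp((dist_to_ptv / s) ** k))


def _correlated_field(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(params.grid_dims)
    sigma = [params.blob_correlation_length / sp for sp in params.spacing]
    return ndimage.gaussian_filter(noise, sigma=sigma)


def generate_patient(
    params: PhantomParams, patient_id: str = "P01", grade: int = 3
) -> tuple[PatientCase, GroundTruth]:
    """Generate one phantom patient; deterministic given ``params`` (incl. seed)."""
    if grade not in range(6):
        raise ValueError(f"grade must be in 0..5, got {grade}")
    rng = np.random.default_rng(params.seed)
    f = float(params.dose_independent_fraction)
    p = params.dose_effect_profile
    p_tot = N_HU_BINS * p
    if f + p_tot.max() >= 1.0:
        raise ValueError(
            f"saturated lung: dose_independent_fraction {f} + max dose-driven "
            f"expectation {p_tot.max():.3f} >= 1"
        )

    lungs, ptv, dist = _lung_and_ptv_masks(params)
    _check_ptv_in_lung_region(params, lungs)
    dose = _dose_field(params, dist)
    lungs_ptv = lungs & ~ptv

    dose_bin = np.clip((dose / DOSE_BIN_WIDTH).astype(int), 0, N_DOSE_BINS - 1)

    # per-(dose bin, HU bin) random effects on the density mixing weights
    sd = params.random_effect_sd
    m = np.exp(sd * rng.standard_normal((N_DOSE_BINS, N_HU_BINS)) - 0.5 * sd * sd)

    pi = params.density_profile / params.density_profile.sum()
    field_vals = _correlated_field(params, rng)

    flat_idx = np.flatnonzero(lungs_ptv)
    if params.stratified_sampling:
        n_steps = N_DOSE_BINS * round(DOSE_BIN_WIDTH / 0.1)
        strata = np.clip((dose.ravel()[flat_idx] / 0.1).astype(int), 0, n_steps - 1)
        strat_bin = np.arange(n_steps) // round(DOSE_BIN_WIDTH / 0.1)
    else:
        strata = dose_bin.ravel()[flat_idx]
        strat_bin = np.arange(N_DOSE_BINS)
    blob_flat, dose_flat, inf_vox_flat, hu_bins_flat = _sample_infiltrate(
        params, rng, flat_idx, strata, strat_bin, field_vals.ravel()[flat_idx], f, p_tot, pi, m
    )
    blob = np.zeros(params.grid_dims, dtype=bool)
    blob.ravel()[blob_flat] = True
    dosedriven = np.zeros(params.grid_dims, dtype=bool)
    dosedriven.ravel()[dose_flat] = True
    infiltrate = blob | dosedriven

    ct = np.full(params.grid_dims, 20.0)  # soft tissue background
    n_lung = int(lungs.sum())
    ct[lungs] = rng.normal(params.baseline_lung_hu_mean, params.baseline_lung_hu_sd, n_lung)
    ct.ravel()[inf_vox_flat] = (
        HU_RANGE[0] + (hu_bins_flat + rng.random(len(hu_bins_flat))) * HU_BIN_WIDTH
    )
    ct[ptv] = 30.0

    vox_ml = float(np.prod(params.spacing)) / 1000.0
    lung_bin_vol = np.array(
        [float((lungs_ptv & (dose_bin == d)).sum()) * vox_ml for d in range(N_DOSE_BINS)]
    )
    vfrac = lung_bin_vol / lung_bin_vol.sum()
    expected_bin_prob = f + (1.0 - f) * p_tot
    total_expected = float(expected_bin_prob @ vfrac)
    attributable_expected = float(((1.0 - f) * (p_tot - p_tot[0])) @ (vfrac))
    truth = GroundTruth(
        patient_id=patient_id,
        dose_independent_fraction=f,
        true_dose_effect_profile=p.copy(),
        true_density_profile=pi.copy(),
        true_attributable_fraction=attributable_expected / total_expected if total_expected > 0 else 0.0,
        true_total_infiltrate_fraction=total_expected,
        realized_infiltrate_fraction=float(infiltrate.sum() / max(lungs_ptv.sum(), 1)),
        random_effects=m,
        lung_bin_volume_ml=lung_bin_vol,
    )
    grid = lambda v: ImageGrid(v, params.spacing, tuple(s / 2 for s in params.spacing))  # noqa: E731
    case = PatientCase(
        patient_id=patient_id,
        grade=grade,
        ct=grid(ct),
        dose=grid(dose),
        lungs_mask=lungs,
        ptv_mask=ptv,
        infiltrate_mask=infiltrate,
        meta={"seed": params.seed},
    )
    return case, truth


def _allocate_counts(n: int, probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Integer allocation of n draws to categories by largest remainder."""
    exact = n * probs
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    if short > 0:
        frac = exact - np.floor(exact)
        order = np.argsort(-(frac + 1e-12 * rng.random(len(probs))))
        counts[order[:short]] += 1
    return counts


def _sample_infiltrate(params, rng, flat_idx, strata, strat_bin, field, f, p_tot, pi, m):
    """Select blob and dose-driven voxels and their HU bins, stratum by stratum.

    A stratum is a 5 Gy dose bin (natural mode) or a 0.1 Gy dose step
    (stratified mode).  Natural mode samples per-voxel Bernoulli memberships
    and multinomial HU bins; stratified mode fixes all counts at their
    (rounded) expectations so the phantom realizes its generative
    expectations exactly, which is what oracle recovery experiments need.
    Blob voxels are always the highest values of the spatially correlated
    field within the stratum, preserving the patchy geometry.
    """
    stratified = params.stratified_sampling
    blob_parts, dose_parts, hu_parts = [], [], []
    order = np.argsort(strata, kind="stable")
    sorted_strata = strata[order]
    bounds = np.searchsorted(sorted_strata, np.arange(len(strat_bin) + 1))
    for s in range(len(strat_bin)):
        members = order[bounds[s]:bounds[s + 1]]
        n = len(members)
        if n == 0:
            continue
        d = int(strat_bin[s])
        vox = flat_idx[members]
        fv = field[members]
        # dose-independent blobs: top field values fill fraction f exactly
        nb = int(round(f * n)) if stratified else int((fv > np.quantile(fv, 1.0 - f)).sum()) if f > 0 else 0
        blob_sel = vox[np.argsort(-fv)[:nb]] if nb else np.empty(0, dtype=np.int64)
        rest = np.setdiff1d(vox, blob_sel, assume_unique=False)
        # dose-driven voxels among the remaining lung
        if stratified:
            k = int(round(p_tot[d] * len(rest)))
            dose_sel = rng.choice(rest, size=k, replace=False) if k else np.empty(0, dtype=np.int64)
        else:
            dose_sel = rest[rng.random(len(rest)) < p_tot[d]]
        for comp_vox, base in ((blob_sel, pi), (dose_sel, _dose_component_profile(params, d))):
            kk = len(comp_vox)
            if kk == 0:
                continue
            wts = base * m[d]
            wts = wts / wts.sum()
            if stratified:
                counts = _allocate_counts(kk, wts, rng)
                bins = rng.permutation(np.repeat(np.arange(N_HU_BINS), counts))
            else:
                bins = rng.choice(N_HU_BINS, size=kk, p=wts)
            (blob_parts if base is pi else dose_parts).append(comp_vox)
            hu_parts.append((comp_vox, bins))
    cat = lambda parts: np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)  # noqa: E731
    vox_all = cat([v for v, _ in hu_parts])
    bins_all = cat([b for _, b in hu_parts]).astype(np.int64)
    return cat(blob_parts), cat(dose_parts), vox_all, bins_all


def _dose_component_profile(params: PhantomParams, d: int) -> np.ndarray:
    """Density mix of the dose-driven component in dose bin d.

    Uniform by default (additive, interaction-free structure); with a nonzero
    per-bin HU shift the mix becomes a dose-shifted unimodal profile, which
    induces a real dose x density interaction.
    """
    if params.dose_hu_shift_per_bin == 0.0:
        return np.full(N_HU_BINS, 1.0 / N_HU_BINS)
    peak = -500.0 + params.dose_hu_shift_per_bin * d
    return gaussian_density_profile(peak_hu=peak, width_hu=params.density_peak_width)


def generate_cohort(
    n_high: int,
    n_low: int,
    params_high: PhantomParams | None = None,
    params_low: PhantomParams | None = None,
    seed: int = 1,
) -> list[tuple[PatientCase, GroundTruth]]:
    """Generate a labeled cohort, high-grade patients first.

    Per-patient dose-independent fractions and density-profile peaks are drawn
    from the cohort ranges configured on the parameter sets (when present);
    everything is reproducible bit-for-bit under a fixed seed.
    """
    if n_high < 0 or n_low < 0:
        raise ValueError("cohort sizes must be non-negative")
    params_high = params_high or default_high_grade_params()
    params_low = params_low or default_low_grade_params()
    rng = np.random.default_rng(seed)
    high_grades = [3, 3, 3, 3, 4, 5]
    out: list[tuple[PatientCase, GroundTruth]] = []
    for i in range(n_high + n_low):
        high = i < n_high
        base = params_high if high else params_low
        pid = f"{'HG' if high else 'LG'}{(i if high else i - n_high) + 1:03d}"
        grade = high_grades[i % len(high_grades)] if high else (i - n_high) % 3
        sub_seed = int(rng.integers(0, 2**31 - 1))
        kwargs: dict = {"seed": sub_seed}
        if base.dose_independent_fraction_range is not None:
            lo, hi = base.dose_independent_fraction_range
            kwargs["dose_independent_fraction"] = float(rng.uniform(lo, hi))
        if base.density_peak_range is not None:
            lo, hi = base.density_peak_range
            kwargs["density_profile"] = gaussian_density_profile(
                peak_hu=float(rng.uniform(lo, hi)), width_hu=base.density_peak_width
            )
        out.append(generate_patient(replace(base, **kwargs), pid, grade))
    return out
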