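# Methods

This note documents the generative model behind the synthetic cohort, the
statistical model and its estimation, the numerical choices, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The observation grid and endpoint

Volumetry works on one co-registered grid per patient (voxel-center
convention, axis-aligned, 0-based indices, half-open bins everywhere).
Structures follow the clinical algebra: `Lungs_PTV` = lung minus PTV,
`INF_PTV` = infiltrate within `Lungs_PTV`, `Lungs_PTV_INF` = the
complement; the latter two partition `Lungs_PTV` exactly, which the test
suite asserts voxel-by-voxel against a set-logic oracle.

Dose is quantized into 0.1 Gy steps by `floor(D / 0.1)` (an epsilon guard
absorbs float representation error on bin edges), grouped into eleven 5 Gy
bins on [0, 55) Gy; CT density into twenty-two 50 HU bins on [−1000, 100) HU.
Voxels outside the density range (dense vessels, air artifacts) are excluded
from the infiltrate numerator and the weight partition; voxels at or above
55 Gy are excluded as spill-over (prescriptions reach 60 Gy, so a small
high-dose shell around the PTV is always excluded) and counted in the QC
report; a `top_bin_clamp` dialect clamps them into the top bin instead.
The full 550 x 22 grid is retained per patient, including zero-lung cells
with `pv = 0, weight = 0` (inert in fitting), so a six-patient cohort always
yields exactly 72,600 rows.

**Endpoint.** `pv(s, h)` is the infiltrate volume with density in bin `h`
and dose in step `s`, divided by the *total* lung-outside-PTV volume in step
`s` (all densities). **Weight.** `w(s, h)` is the lung-outside-PTV volume in
the cell, divided by the patient's total lung-outside-PTV volume; weights
partition the lung volume over the grid (closure <= 1, with the deficit equal
to the excluded HU/spill volume).

**Down-sampling.** Scalars are block-averaged with exact fractional-overlap
weighting along each axis (volume-preserving, no silent cropping for
non-integer ratios); a coarse mask voxel is set when the fine mask covers
more than 50% of its volume. Nearest-neighbor resampling is available as an
opt-in dialect for pipelines that interpolate binary masks. The >50% rule
was chosen over nearest-neighbor as the default because it states the intent
directly; the two disagree in general.

## 2. The synthetic cohort

Each phantom patient has two ellipsoid half-lungs (semi-axes 62/105/78 mm)
on a 96 x 96 x 48 grid at 4 mm isotropic spacing (the finer 128 x 128 x 66
analysis grid is a config option), a spherical PTV (radius 27 mm) at the
medial lung boundary, and a dose field

```
D(r) = D_presc * 2 / (1 + exp((r / s)^k))
```

with `r` the distance to the PTV surface, `D_presc = 60 Gy`, scale
`s = 36 mm` and shape `k = 1.5`. The scale and shape were calibrated once so
the lung dose metrics sit in the clinically reported neighborhood for this
treatment setting (MLD 16.9 Gy, V5 70.9%, V20 32.2%); they were fixed before
any acceptance test was written.

The infiltrate has two components on the lung outside the PTV:

- **Dose-independent blobs** (fraction `f` of lung-outside-PTV): a Gaussian
  random field smoothed at the blob correlation length (default 12 mm) is
  thresholded at the `1 − f` quantile *within each 5 Gy dose bin*, so the
  realized dose-independent fraction is exactly flat across dose bins — the
  defining property of a dose-independent process — while the patchy spatial
  geometry is preserved within bins.
- **Dose-driven voxels**: sampled among the remaining lung with probability
  `22 * p[d]` in dose bin `d`, where `p` is the per-density-bin dose-effect
  profile (default: linear ramp from 0 to 0.015 per stratum at [50,55) Gy).
  The realized infiltrate probability in bin `d` is `f + (1−f) * 22 * p[d]`,
  and the generator's true per-stratum dose effect relative to the [0,5) Gy
  bin is `(1−f) * (p[d] − p[0])`. A configuration with
  `f + max_d 22 p[d] >= 1` is rejected as a saturated lung.

Infiltrated voxels are re-assigned CT densities: blob voxels draw their
50 HU bin from a unimodal profile (Gaussian over HU, default peak −500 HU,
width 150 HU, plus uniform within-bin jitter), dose-driven voxels draw
uniformly over the 22 bins. This makes the expected `pv` surface *exactly
additive* in (dose bin, density bin) — the no-interaction structure the
analysis model assumes — because a dose-driven increment that is uniform
over density strata is precisely a dose effect that is the same in every
stratum. An optional per-bin HU shift of the dose-driven component creates
a genuine dose x density interaction for power studies. Non-infiltrated
lung is aerated parenchyma at −850 ± 40 HU (a plausible choice, not a
literature fit); the rare baseline draws below −1000 HU exercise the QC
exclusion path.

**Random effects** are realized per (patient, dose bin, density bin) as
independent log-normal factors (default sd 0.2, mean-one) multiplying the
density-bin mixing weights within each (patient, dose bin), renormalized.
This modulates the density profile per patient and dose bin — the location
of the density peak varies from patient to patient — while keeping the
dose-bin marginal load at its controlled target, and it matches the
crossed random-intercept indexing of the analysis model exactly.

**Cohort defaults.** High-grade patients draw their dose-independent
fraction uniformly from 17.9–58.4% (the reported [0,5) Gy-bin range for
high-grade pneumonitis) and their density-profile peak from U(−600, −400) HU;
low-grade comparison patients draw from 2–12%, strictly below the high-grade
range. Grades are 3,3,3,3,4,5 for the high cohort and 0–2 cycling for the
low cohort. Everything is reproducible bit-for-bit under a fixed seed
(per-patient seeds derive from the cohort seed).

**Stratified (oracle) mode.** With `stratified_sampling=True` the generator
fixes all counts at their rounded expectations per 0.1 Gy dose step
(largest-remainder allocation of the blob fraction, the dose-driven count,
and the HU-bin counts), so the phantom realizes its generative expectations
essentially exactly. This mode exists for estimator-validation experiments
(parameter recovery, attribution recovery, null calibration); the default
per-voxel sampling is the study condition. The reason this distinction
matters is in section 4.

## 3. Estimation

The model (README, section "The endpoint and the model") has a single
random-intercept variance component over (patient, dose bin, density bin)
cells and observation weights on the residual precision. The engine profiles
the REML (or ML) criterion down to the variance ratio
`lambda = sigma_u^2 / sigma_e^2`: for fixed lambda the GLS solution,
profiled residual variance and all determinants are closed-form via the
Woodbury identity applied group-block by group-block, and the scalar lambda
is minimized by bounded search (tolerance 1e-8 on log-lambda, max 200
iterations; deterministic given the data). A boundary solution pins
`sigma_u^2 = 0` with a warning. The engine is cross-checked in the test
suite against a dense-matrix REML oracle and against R `lme4` (weighted
REML, same structure) on small data.

- Zero-weight observations are removed before fitting; deleting them changes
  nothing (asserted to 1e-10).
- Denominator degrees of freedom: Satterthwaite, via numeric gradients of
  contrast variances with respect to `(sigma_u^2, sigma_e^2)` and the
  numeric REML information; multi-row contrasts use the Fai–Cornelius
  combination of per-eigenvector single-df approximations. At a boundary fit
  the residual df are used and flagged.
- AIC across dose forms (step / linear / linear-quadratic / constant) comes
  from ML fits, because REML criteria are not comparable across
  fixed-effect structures; SAS-style REML AICs are reported alongside.
  Continuous dose forms use the 0.1 Gy step midpoint, not the 5 Gy bin
  midpoint.
- Normal-scores reanalysis: Blom scores (`(r − 3/8)/(n + 1/4)`, average
  ranks for ties) computed within patient over all non-zero-weight cells;
  the refit is invariant under strictly monotone endpoint transforms.
- The row-mean-scores Cochran–Mantel–Haenszel statistic for between-patient
  density-distribution differences is the single-stratum quadratic form
  `U' V^{-1} U` under the multivariate hypergeometric null, referred to
  chi-square with (patients − 1) df; it is affine-invariant in the column
  scores and validated against a permutation oracle.
- ROC/AUC per dose bin: AUC is the rank statistic (identical to normalized
  Mann–Whitney U, asserted as an oracle identity), the p-value is the
  likelihood-ratio test of the single-feature logistic model (under complete
  separation the supremum log-likelihood is 0, so the LR statistic equals
  `−2 ll_null` and the coefficient is flagged non-finite), confidence
  intervals use DeLong placements, and per-bin significance is declared at
  alpha = 0.002 (Bonferroni-style multiplicity control over the 11 bins).
- Ward clustering standardizes features by default ('none' and PCA
  whitening are options; the original SAS Aceclus preprocessing is
  under-documented, and no preprocessing changes the purity behavior noted
  below). Missing bins are imputed as 0 with a flag; constant feature sets
  are an error.
- The dosimetric group comparison uses the unpaired rank-sum test by
  default; a signed-rank flag exists for genuinely paired designs. The
  Kruskal–Wallis comparison across dose bins applies to the per-patient
  lung-volume fractions per bin.

**Attribution.** With reference-cell coding, whatever infiltrate exists in
the [0,5) Gy bin is by construction not dose-attributable; the attributable
volume is `sum_d 22 * alpha_d * V_p(d)` (additivity over the 22 strata holds
because there is no interaction), clipped to [0, total infiltrate volume].
The dose-independent component is `22 * mu + sum_h beta_h` with a
delta-method SE. The report gives mean, median and range of the per-patient
attributable fractions.

## 4. A known bias of the weighted estimator, and what the tests validate

The weights are *realized* per-cell lung volumes, and in infiltrate-typical
density bins the lung volume of a cell is dominated by the infiltrate voxels
themselves. Within the tiny cells of the 0.1 Gy x 50 HU grid this makes the
weight positively correlated with the endpoint, so the weighted fixed
effects are inflated — and because cells shrink with dose, the inflation is
dose-shaped. The effect is intrinsic to the endpoint definition (any random
mechanism that adds infiltrate to a cell also adds that cell's weight), only
weakly resolution-dependent, and applies to real data analysed this way just
as to the phantom's natural sampling mode.

Consequently the estimator-validation experiments (parameter recovery within
confidence intervals, attribution recovery within ±3 percentage points,
type-I error of the dose F-test under a null profile) run on the stratified
oracle mode, where cell contents equal their expectations and the check
isolates the estimator itself. On the natural-sampling default cohort the
significance tests, monotonicity, leave-one-out stability, AIC orderings and
discrimination results all hold, but fixed-effect *point estimates* carry
the inflation described above (roughly +50% on the dose profile at the
default resolution). Interpret absolute effect sizes from such fits — and
from comparable analyses of real data — with this in mind.

A related structural fact: the two grade groups differ mainly in their
dose-independent fraction, which is also the dominant axis of within-group
variation (the high-grade range 17.9–58.4% is wide). Rank-based and
single-feature discrimination are unaffected (AUC 1.0 below 5 Gy), but
Ward's minimum-variance bipartition is not forced to follow the grade
boundary: over repeated cohorts the 2-cluster cut is pure in roughly 40% of
seeds and always >= 97% pure. The package reports the purity rather than
assuming it.

## 5. Problem sizes and determinism

Default experiment sizes: 6 high-grade patients (72,600 observations) for
model fitting; 6 + 104 patients for discrimination; 10 seeds for recovery
experiments and 100 seeds for null calibration, at the default 96 x 96 x 48
grid. These sizes keep each experiment in the seconds-to-a-couple-of-minutes
range while leaving the statistical conclusions stable across seeds. All
randomness flows from explicit integer seeds; model fitting is
deterministic given the data.
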