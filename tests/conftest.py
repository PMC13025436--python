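"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorized code paths: they
loop over voxels / clusters / permutations so that agreement is evidence,
not tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

import pneumovox as pv
from pneumovox.grids import ImageGrid, PatientCase

# ---------------------------------------------------------------- toy cases


def build_toy_case(seed: int = 0, dims=(8, 8, 4), patient_id: str = "TOY", grade: int = 3,
                   max_dose: float = 60.0) -> PatientCase:
    """Small random case with HU and dose values straddling all bin edges."""
    rng = np.random.default_rng(seed)
    lungs = rng.random(dims) < 0.7
    if not lungs.any():
        lungs[0, 0, 0] = True
    ptv = rng.random(dims) < 0.1
    inf = (rng.random(dims) < 0.4) & lungs
    ct = rng.uniform(-1100.0, 200.0, dims)        # includes out-of-range HU
    dose = rng.uniform(0.0, max_dose, dims)       # includes spill-over dose
    spacing = (10.0, 10.0, 10.0)
    return PatientCase(
        patient_id=patient_id, grade=grade,
        ct=ImageGrid(ct, spacing), dose=ImageGrid(dose, spacing),
        lungs_mask=lungs, ptv_mask=ptv, infiltrate_mask=inf,
    )


# ------------------------------------------------------------ voxel oracles


def oracle_observations(case: PatientCase, scheme: pv.BinningScheme):
    """Triple voxel loop computing pv, weight and per-step lung volume."""
    nx, ny, nz = case.ct.dims
    n_steps, n_hu = scheme.n_dose_steps, scheme.n_hu_bins
    vox = case.ct.voxel_volume_ml
    lung_cell = np.zeros((n_steps, n_hu))
    inf_cell = np.zeros((n_steps, n_hu))
    step_lung = np.zeros(n_steps)
    v_p = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not case.lungs_mask[i, j, k] or case.ptv_mask[i, j, k]:
                    continue
                v_p += vox
                d = case.dose.values[i, j, k]
                s = int(np.floor(d / scheme.dose_step + 1e-9))
                if s >= n_steps:
                    continue
                step_lung[s] += vox
                hu = case.ct.values[i, j, k]
                h = int(np.floor((hu - scheme.hu_range[0]) / scheme.hu_bin_width + 1e-9))
                if h < 0 or h >= n_hu:
                    continue
                lung_cell[s, h] += vox
                if case.infiltrate_mask[i, j, k]:
                    inf_cell[s, h] += vox
    with np.errstate(divide="ignore", invalid="ignore"):
        pvv = np.where(step_lung[:, None] > 0, inf_cell / np.where(step_lung[:, None] > 0, step_lung[:, None], 1), 0.0)
    weight = lung_cell / v_p
    return pvv, weight, step_lung, v_p


def oracle_dose_metrics(case: PatientCase):
    nx, ny, nz = case.ct.dims
    doses, hus = [], []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if case.lungs_mask[i, j, k] and not case.ptv_mask[i, j, k]:
                    doses.append(case.dose.values[i, j, k])
                    if case.infiltrate_mask[i, j, k]:
                        hus.append(case.ct.values[i, j, k])
    doses = np.array(doses)
    return (
        doses.mean(),
        100.0 * (doses >= 5).mean(),
        100.0 * (doses >= 20).mean(),
        np.mean(hus) if hus else np.nan,
    )


def oracle_downsample_mask(mask: np.ndarray, target_dims):
    """Exact fractional coverage of each coarse voxel, by direct interval overlap."""
    src = mask.shape
    cov = np.zeros(target_dims)
    r = [s / t for s, t in zip(src, target_dims)]
    for a in range(target_dims[0]):
        for b in range(target_dims[1]):
            for c in range(target_dims[2]):
                tot = 0.0
                lo = [a * r[0], b * r[1], c * r[2]]
                hi = [(a + 1) * r[0], (b + 1) * r[1], (c + 1) * r[2]]
                for i in range(int(lo[0]), min(int(np.ceil(hi[0])), src[0])):
                    oi = min(hi[0], i + 1) - max(lo[0], i)
                    for j in range(int(lo[1]), min(int(np.ceil(hi[1])), src[1])):
                        oj = min(hi[1], j + 1) - max(lo[1], j)
                        for k in range(int(lo[2]), min(int(np.ceil(hi[2])), src[2])):
                            ok = min(hi[2], k + 1) - max(lo[2], k)
                            if mask[i, j, k]:
                                tot += oi * oj * ok
                cov[a, b, c] = tot / (r[0] * r[1] * r[2])
    return cov


def oracle_ward(points: np.ndarray):
    """Greedy Ward linkage on 1-D/low-D points via explicit ESS bookkeeping.

    Returns the sorted list of merge heights (scipy convention:
    sqrt(2 * ESS increase)) and the member sets merged at each step.
    """
    clusters = [[i] for i in range(len(points))]
    heights, merges = [], []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a = points[clusters[i]]
                b = points[clusters[j]]
                na, nb = len(a), len(b)
                d2 = np.sum((a.mean(axis=0) - b.mean(axis=0)) ** 2)
                delta = na * nb / (na + nb) * d2
                if best is None or delta < best[0]:
                    best = (delta, i, j)
        delta, i, j = best
        heights.append(np.sqrt(2.0 * delta))
        merges.append((frozenset(clusters[i]), frozenset(clusters[j])))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [clusters[i] + clusters[j]]
    return heights, merges


def oracle_cmh_permutation(counts: np.ndarray, n_perm: int = 3000, seed: int = 0):
    """Permutation p-value for the row-mean-scores statistic on integer counts."""
    from pneumovox.dose_response import density_distribution_test

    counts = np.asarray(counts, dtype=int)
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(counts.shape[0]), counts.sum(axis=1))
    cols = np.concatenate([np.repeat(np.arange(counts.shape[1]), r) for r in counts])
    obs = density_distribution_test(counts)["statistic"]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(cols)
        tab = np.zeros_like(counts)
        np.add.at(tab, (rows, perm), 1)
        if density_distribution_test(tab)["statistic"] >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def high_cohort():
    """The default six-patient high-grade phantom cohort (study conditions)."""
    return pv.generate_cohort(6, 0, seed=1)


@pytest.fixture(scope="session")
def high_table(high_cohort):
    return pv.concat_observations(
        [pv.compute_observations(c) for c, _ in high_cohort]
    )


@pytest.fixture(scope="session")
def step_fit(high_table):
    return pv.fit_mixed(high_table)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Stratified-sampling oracle cohort with known fixed-effect truth."""
    from dataclasses import replace

    base = pv.PhantomParams(
        stratified_sampling=True, dose_independent_fraction=0.4, random_effect_sd=0.2
    )
    return [pv.generate_patient(replace(base, seed=40 + i), f"P{i}", 3) for i in range(6)]


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    table = pv.concat_observations(
        [pv.compute_observations(c) for c, _ in recovery_cohort]
    )
    return pv.fit_mixed(table), table
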