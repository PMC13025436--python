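"""Volumetry: structure algebra, resampling, binning and metrics vs voxel oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pneumovox as pv
from pneumovox.grids import ImageGrid

from .conftest import (
    build_toy_case,
    oracle_dose_metrics,
    oracle_downsample_mask,
    oracle_observations,
)


def test_default_scheme_counts():
    s = pv.BinningScheme()
    assert s.n_dose_steps == 550 and s.n_dose_bins == 11 and s.n_hu_bins == 22
    assert s.steps_per_bin == 50


@pytest.mark.parametrize(
    "kwargs", [{"dose_step": -0.1}, {"hu_bin_width": 37.0}, {"dose_bin_width": 5.3},
               {"dose_range": (0.0, 54.0), "dose_bin_width": 5.0}]
)
def test_invalid_schemes_rejected(kwargs):
    with pytest.raises(ValueError):
        pv.BinningScheme(**kwargs)


# ------------------------------------------------------------ structures


@pytest.mark.parametrize("seed", range(4))
def test_structure_algebra_matches_set_logic_oracle(seed):
    case = build_toy_case(seed)
    inf_ptv, lungs_ptv, lungs_ptv_inf = pv.derive_structures(case)
    for idx in np.ndindex(*case.ct.dims):
        lung = case.lungs_mask[idx] and not case.ptv_mask[idx]
        inf = case.infiltrate_mask[idx]
        assert lungs_ptv[idx] == lung
        assert inf_ptv[idx] == (lung and inf)
        assert lungs_ptv_inf[idx] == (lung and not inf)
    # the two sub-structures partition lungs_ptv
    assert not (inf_ptv & lungs_ptv_inf).any()
    assert ((inf_ptv | lungs_ptv_inf) == lungs_ptv).all()


def test_structure_algebra_degenerate_masks():
    case = build_toy_case(1)
    empty = case.with_grids(infiltrate_mask=np.zeros(case.ct.dims, dtype=bool))
    inf_ptv, lungs_ptv, lungs_ptv_inf = pv.derive_structures(empty)
    assert not inf_ptv.any() and (lungs_ptv_inf == lungs_ptv).all()
    full = case.with_grids(infiltrate_mask=case.lungs_mask.copy())
    inf_ptv, lungs_ptv, lungs_ptv_inf = pv.derive_structures(full)
    assert (inf_ptv == lungs_ptv).all() and not lungs_ptv_inf.any()
    with pytest.raises(ValueError, match="lungs"):
        pv.derive_structures(case.with_grids(lungs_mask=np.zeros(case.ct.dims, dtype=bool)))


# ------------------------------------------------------------ resampling


def test_downsample_uniform_field_is_invariant():
    case = build_toy_case(0, dims=(16, 16, 8))
    case.ct.values[:] = -700.0
    coarse = pv.downsample_case(case, (8, 8, 4))
    assert np.allclose(coarse.ct.values, -700.0)
    assert coarse.ct.spacing == (20.0, 20.0, 20.0)


def test_half_coverage_rule_single_octant_mask():
    """A mask covering one octant of each 2x2x2 block (12.5%) vanishes."""
    dims = (8, 8, 4)
    mask = np.zeros(dims, dtype=bool)
    mask[::2, ::2, ::2] = True
    case = build_toy_case(0, dims=dims).with_grids(lungs_mask=np.ones(dims, bool),
                                                   infiltrate_mask=mask)
    coarse = pv.downsample_case(case, (4, 4, 2))
    assert not coarse.infiltrate_mask.any()
    assert coarse.lungs_mask.all()


@pytest.mark.parametrize("dims,target", [((16, 16, 8), (8, 8, 4)), ((9, 6, 4), (4, 3, 2))])
def test_downsample_masks_match_fractional_overlap_oracle(dims, target):
    case = build_toy_case(3, dims=dims)
    coarse = pv.downsample_case(case, target)
    lungs_cov = oracle_downsample_mask(case.lungs_mask, target)
    ptv_cov = oracle_downsample_mask(case.ptv_mask, target)
    inf_cov = oracle_downsample_mask(case.infiltrate_mask, target)
    assert np.array_equal(coarse.lungs_mask, lungs_cov > 0.5)
    assert np.array_equal(coarse.ptv_mask, ptv_cov > 0.5)
    # the case container re-clips infiltrate to the coarse lungs
    assert np.array_equal(coarse.infiltrate_mask, (inf_cov > 0.5) & (lungs_cov > 0.5))
    # block-averaged scalars preserve the volume-weighted mean
    assert np.isclose(coarse.dose.values.mean(), case.dose.values.mean())


def test_downsample_rejects_upsampling():
    case = build_toy_case(0)
    with pytest.raises(ValueError):
        pv.downsample_case(case, (16, 8, 4))


def test_nearest_neighbor_dialect():
    case = build_toy_case(2, dims=(8, 8, 4))
    coarse = pv.downsample_case(case, (4, 4, 2), method="nearest")
    # nearest sampling picks the fine voxel containing each coarse center
    assert coarse.ct.values[0, 0, 0] in case.ct.values[:2, :2, :2]


# ------------------------------------------------------------ quantization


def test_dose_step_examples():
    grid = ImageGrid(np.array([[[0.0, 17.23, 0.05, 54.99]]]), (1, 1, 1))
    assert pv.quantize_dose(grid, 0.1).ravel().tolist() == [0, 172, 0, 549]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=80), min_size=1, max_size=20))
def test_quantize_matches_floor_oracle(doses):
    arr = np.array(doses).reshape(1, 1, -1)
    out = pv.quantize_dose(ImageGrid(arr, (1, 1, 1)), 0.1)
    expect = [int(np.floor(d / 0.1 + 1e-9)) for d in doses]
    assert out.ravel().tolist() == expect


def test_quantize_negative_dose_is_an_error():
    with pytest.raises(ValueError):
        pv.quantize_dose(ImageGrid(np.full((1, 1, 1), -0.1), (1, 1, 1)))


# ------------------------------------------------------------ observations


@pytest.mark.parametrize("seed", range(3))
def test_observations_match_voxel_loop_oracle(seed):
    case = build_toy_case(seed)
    scheme = pv.BinningScheme()
    obs = pv.compute_observations(case, scheme)
    pvv, weight, step_lung, v_p = oracle_observations(case, scheme)
    got_pv = obs.data["pv"].to_numpy().reshape(550, 22)
    got_w = obs.data["weight"].to_numpy().reshape(550, 22)
    assert np.allclose(got_pv, pvv, rtol=1e-12, atol=0)
    assert np.allclose(got_w, weight, rtol=1e-12, atol=0)
    assert np.allclose(obs.step_lung_volume_ml[case.patient_id], step_lung, rtol=1e-12)
    assert np.isclose(obs.lung_volume_ml[case.patient_id], v_p, rtol=1e-12)


def test_observation_grid_is_complete_with_inert_rows():
    obs = pv.compute_observations(build_toy_case(1))
    assert len(obs.data) == 550 * 22
    zero = obs.data[obs.data["weight"] == 0]
    assert (zero["pv"] == 0).all()


def test_six_patient_cohort_has_72600_rows():
    tables = [pv.compute_observations(build_toy_case(s, patient_id=f"T{s}")) for s in range(6)]
    assert len(pv.concat_observations(tables).data) == 72600


def test_empty_infiltrate_keeps_weight_partition():
    case = build_toy_case(2)
    case = case.with_grids(infiltrate_mask=np.zeros(case.ct.dims, dtype=bool))
    obs = pv.compute_observations(case)
    assert (obs.data["pv"] == 0).all()
    in_range = (obs.data.groupby("patient_id")["weight"].sum()).iloc[0]
    assert 0 < in_range <= 1 + 1e-9


def test_weight_closure_and_pv_normalization(high_table):
    for pid in high_table.patients:
        sub = high_table.data[high_table.data["patient_id"] == pid]
        assert sub["weight"].sum() <= 1 + 1e-9
        per_step = sub.groupby("dose_step")["pv"].sum()
        assert (per_step <= 1 + 1e-9).all()
        assert (sub["pv"] >= 0).all() and (sub["pv"] <= 1).all()


def test_all_zero_lung_is_an_error():
    case = build_toy_case(0)
    case = case.with_grids(ptv_mask=np.ones(case.ct.dims, dtype=bool))
    with pytest.raises(ValueError):
        pv.compute_observations(case)


def test_top_bin_clamp_dialect_counts_spill_into_top_bin():
    case = build_toy_case(4, max_dose=70.0)
    open_scheme = pv.BinningScheme()
    clamped = pv.BinningScheme(top_bin_clamp=True)
    o1 = pv.compute_observations(case, open_scheme)
    o2 = pv.compute_observations(case, clamped)
    assert o1.qc[case.patient_id]["spill_dose_voxels"] > 0
    assert o2.step_lung_volume_ml[case.patient_id].sum() > o1.step_lung_volume_ml[case.patient_id].sum()


# ------------------------------------------------------------ features, metrics


@pytest.mark.parametrize("seed", range(3))
def test_dose_bin_features_match_oracle(seed):
    case = build_toy_case(seed)
    scheme = pv.BinningScheme()
    feats = pv.dose_bin_features(pv.compute_observations(case, scheme)).values.to_numpy()[0]
    pvv, weight, step_lung, v_p = oracle_observations(case, scheme)
    inf_step = (pvv * step_lung[:, None]).sum(axis=1)
    for d in range(11):
        lung = step_lung[d * 50:(d + 1) * 50].sum()
        inf = inf_step[d * 50:(d + 1) * 50].sum()
        if lung > 0:
            assert np.isclose(feats[d], inf / lung, rtol=1e-12)
        else:
            assert np.isnan(feats[d])


def test_features_full_and_empty_infiltrate():
    case = build_toy_case(5)
    full = case.with_grids(infiltrate_mask=case.lungs_mask & ~case.ptv_mask)
    # keep HU inside the analysis range so every lung voxel is countable
    full.ct.values[:] = -500.0
    feats = pv.dose_bin_features(pv.compute_observations(full)).values.to_numpy()[0]
    assert np.allclose(feats[~np.isnan(feats)], 1.0)


def test_dose_metrics_uniform_and_oracle():
    case = build_toy_case(0)
    case.dose.values[:] = 10.0
    m = pv.dose_metrics(case)
    assert (m.mean_lung_dose, m.v5, m.v20) == (10.0, 100.0, 0.0)
    case.dose.values[:] = 0.0
    m0 = pv.dose_metrics(case)
    assert (m0.mean_lung_dose, m0.v5, m0.v20) == (0.0, 0.0, 0.0)
    rnd = build_toy_case(7)
    got = pv.dose_metrics(rnd)
    mld, v5, v20, hu = oracle_dose_metrics(rnd)
    assert np.isclose(got.mean_lung_dose, mld, rtol=1e-12)
    assert np.isclose(got.v5, v5, rtol=1e-12)
    assert np.isclose(got.v20, v20, rtol=1e-12)
    assert np.isclose(got.mean_infiltrate_hu, hu, rtol=1e-12)
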