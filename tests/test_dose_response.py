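"""Dose-response model battery: recovery, null calibration, tests and refits."""

from dataclasses import replace

import numpy as np
import pytest

import pneumovox as pv
from pneumovox.dose_response import blom_normal_scores

from .conftest import oracle_cmh_permutation


def _stratified_cohort(seed0, npat=6, **kwargs):
    base = pv.PhantomParams(stratified_sampling=True, dose_independent_fraction=0.4,
                            **kwargs)
    cases = [pv.generate_patient(replace(base, seed=seed0 + i), f"P{i}", 3)
             for i in range(npat)]
    table = pv.concat_observations([pv.compute_observations(c) for c, _ in cases])
    return cases, table


# ------------------------------------------------------------ core fit


def test_calibrated_cohort_dose_and_density_highly_significant(step_fit):
    assert step_fit.tests["dose"]["p"] < 1e-4
    assert step_fit.tests["density"]["p"] < 1e-4
    assert step_fit.monotone_alpha
    assert step_fit.sigma2_u > 0 and step_fit.sigma2_e > 0


def test_fit_requires_two_patients(high_table):
    one = pv.subset_patients(high_table, [high_table.patients[0]])
    with pytest.raises(ValueError, match="2 patients"):
        pv.fit_mixed(one)


def test_parameter_recovery_in_confidence_intervals(recovery_fit, recovery_cohort):
    fit, _ = recovery_fit
    ta = recovery_cohort[0][1].true_alpha()
    tb = recovery_cohort[0][1].true_beta()
    a_in = np.sum((fit.alpha_ci[1:, 0] <= ta[1:]) & (ta[1:] <= fit.alpha_ci[1:, 1]))
    b_in = np.sum((fit.beta_ci[1:, 0] <= tb[1:]) & (tb[1:] <= fit.beta_ci[1:, 1]))
    assert a_in >= 9 and b_in >= 19  # acceptance runs the full 10-seed average


def test_null_phantom_dose_test_holds_level():
    hits = 0
    for s in range(10):
        _, table = _stratified_cohort(5000 + 97 * s, random_effect_sd=0.0,
                                      dose_effect_profile=np.zeros(11))
        if pv.fit_mixed(table).tests["dose"]["p"] < 0.01:
            hits += 1
    assert hits <= 1


def test_step_fit_with_one_dose_bin_equals_constant_fit():
    scheme = pv.BinningScheme(dose_range=(0.0, 5.0))
    case, _ = pv.generate_patient(pv.PhantomParams(seed=8), "A", 3)
    case2, _ = pv.generate_patient(pv.PhantomParams(seed=9), "B", 3)
    table = pv.concat_observations(
        [pv.compute_observations(case, scheme), pv.compute_observations(case2, scheme)]
    )
    f_step = pv.fit_mixed(table, pv.ModelSpec(dose_form="step"))
    f_const = pv.fit_mixed(table, pv.ModelSpec(dose_form="constant"))
    assert np.allclose(f_step.engine.params, f_const.engine.params)
    assert np.isclose(f_step.engine.loglik, f_const.engine.loglik)


def test_deleting_zero_weight_rows_does_not_change_fit(high_table):
    fit = pv.fit_mixed(high_table)
    pruned = pv.ObservationTable(
        data=high_table.data[high_table.data["weight"] > 0].reset_index(drop=True),
        scheme=high_table.scheme,
        lung_volume_ml=high_table.lung_volume_ml,
        step_lung_volume_ml=high_table.step_lung_volume_ml,
        grades=high_table.grades,
    )
    fit2 = pv.fit_mixed(pruned)
    assert np.allclose(fit.engine.params, fit2.engine.params, atol=1e-10)


# ------------------------------------------------------------ interaction


def test_interaction_absent_in_additive_phantom(high_table):
    res = pv.test_interaction(high_table)
    assert res["p"] > 0.05


def test_interaction_detected_when_dose_shifts_density():
    _, table = _stratified_cohort(900, dose_hu_shift_per_bin=30.0)
    assert pv.test_interaction(table)["p"] < 0.01


def test_interaction_needs_multiple_patients(high_table):
    one = pv.subset_patients(high_table, [high_table.patients[0]])
    with pytest.raises(ValueError):
        pv.test_interaction(one)


# ------------------------------------------------------------ model comparison


def test_linear_truth_prefers_linear_over_constant(high_table):
    forms = pv.compare_dose_forms(high_table)
    assert forms.loc["linear", "aic"] < forms.loc["constant", "aic"]
    assert forms.loc["linear", "dose_gy_p"] < 1e-4
    assert forms.loc["linear_quadratic", "dose_gy2_p"] > 0.01  # quadratic unnecessary


def test_zero_effect_constant_within_two_aic_of_linear():
    wins = 0
    for s in range(3):
        _, table = _stratified_cohort(7000 + 31 * s, dose_effect_profile=np.zeros(11))
        forms = pv.compare_dose_forms(table)
        if abs(forms.loc["constant", "aic"] - forms.loc["linear", "aic"]) <= 2.0:
            wins += 1
    assert wins >= 2


def test_saturating_truth_prefers_step_over_linear():
    prof = 0.015 * np.minimum(np.arange(11) / 4.0, 1.0)
    _, table = _stratified_cohort(50, dose_effect_profile=prof)
    forms = pv.compare_dose_forms(table)
    assert forms.loc["step", "aic"] <= forms.loc["linear", "aic"]


# ------------------------------------------------------------ robustness refits


def test_leave_one_patient_out_stays_significant_and_monotone(high_table):
    lopo = pv.leave_one_patient_out(high_table)
    assert len(lopo) == 6
    assert (lopo["dose_p"] < 1e-4).all()
    assert lopo["monotone"].all()


def test_leave_one_out_needs_three_patients(high_table):
    two = pv.subset_patients(high_table, high_table.patients[:2])
    with pytest.raises(ValueError, match="3 patients"):
        pv.leave_one_patient_out(two)


def test_per_patient_slopes_all_positive(high_table):
    slopes = pv.fit_per_patient(high_table)
    assert (slopes["slope"] > 0).all()
    assert (slopes["p"] < 0.002).all()


def test_zero_dose_patient_slope_ci_covers_zero():
    base = pv.PhantomParams(seed=3, dose_effect_profile=np.zeros(11),
                            stratified_sampling=True, dose_independent_fraction=0.3)
    case, _ = pv.generate_patient(base, "Z", 3)
    table = pv.compute_observations(case)
    slopes = pv.fit_per_patient(table)
    assert abs(slopes["slope"].iloc[0]) < 2.5 * slopes["se"].iloc[0]


# ------------------------------------------------------------ normal scores


def test_normal_scores_refit_monotone_and_significant(high_table):
    ns = pv.normal_scores_refit(high_table)
    assert ns.tests["dose"]["p"] < 1e-4
    assert ns.monotone_alpha


def test_normal_scores_invariant_under_monotone_transform(high_table):
    transformed = high_table.data.copy()
    # an exactly monotone (rank-preserving, collision-free) nonlinear map:
    # send the sorted unique pv values to an increasing random sequence
    uniq = np.unique(transformed["pv"].to_numpy())
    repl = np.cumsum(np.random.default_rng(0).uniform(0.1, 1.0, len(uniq)))
    transformed["pv"] = repl[np.searchsorted(uniq, transformed["pv"].to_numpy())]
    t2 = pv.ObservationTable(
        data=transformed, scheme=high_table.scheme,
        lung_volume_ml=high_table.lung_volume_ml,
        step_lung_volume_ml=high_table.step_lung_volume_ml,
        grades=high_table.grades,
    )
    f1 = pv.normal_scores_refit(high_table)
    f2 = pv.normal_scores_refit(t2)
    assert np.allclose(f1.engine.params, f2.engine.params, atol=1e-12)


def test_blom_scores_handle_ties_by_average_rank():
    s = blom_normal_scores(np.array([1.0, 1.0, 2.0, 3.0]))
    assert s[0] == s[1] < s[2] < s[3]
    const = blom_normal_scores(np.full(5, 0.7))
    assert np.allclose(const, const[0])


# ------------------------------------------------------------ CMH


def test_cmh_two_by_two_matches_hand_computation():
    # table [[10, 20], [25, 5]]: N=60, scores (0,1)
    M = np.array([[10, 20], [25, 5]])
    res = pv.density_distribution_test(M)
    N, n1, nj1 = 60, 30, 25
    mu = nj1 / N
    va = (0 - mu) ** 2 * 35 / N + (1 - mu) ** 2 * 25 / N
    U = 20 - n1 * mu
    V = va / (N - 1) * (N * n1 - n1 * n1)
    assert np.isclose(res["statistic"], U * U / V, rtol=1e-12)
    assert res["df"] == 1


def test_cmh_identical_rows_is_null():
    M = np.tile([5, 10, 5], (4, 1))
    res = pv.density_distribution_test(M)
    assert res["statistic"] < 1e-9 and res["p"] > 0.999


def test_cmh_location_shift_detected_and_matches_permutation_oracle():
    rng = np.random.default_rng(0)
    M = np.vstack([
        rng.multinomial(60, [0.5, 0.3, 0.15, 0.05]),
        rng.multinomial(60, [0.05, 0.15, 0.3, 0.5]),
        rng.multinomial(60, [0.25, 0.25, 0.25, 0.25]),
    ])
    res = pv.density_distribution_test(M)
    assert res["p"] < 0.01
    p_perm = oracle_cmh_permutation(M, n_perm=3000)
    assert abs(res["p"] - p_perm) < 0.01


def test_cmh_affine_score_invariance():
    M = np.array([[3, 7, 2], [6, 1, 9]])
    a = pv.density_distribution_test(M, scores=np.array([0.0, 1.0, 2.0]))
    b = pv.density_distribution_test(M, scores=np.array([-975.0, -925.0, -875.0]))
    assert np.isclose(a["statistic"], b["statistic"], rtol=1e-10)


def test_patient_hu_volumes_total_matches_infiltrate_volume(high_table, high_cohort):
    vols = pv.patient_hu_volumes(high_table)
    for case, _ in high_cohort:
        inf_ml = (case.infiltrate_mask & ~case.ptv_mask).sum() * case.ct.voxel_volume_ml
        got = vols.loc[case.patient_id].sum()
        # in-range, in-dose-grid infiltrate only; tiny spill/HU exclusions allowed
        assert got <= inf_ml + 1e-9
        assert got > 0.95 * inf_ml
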