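"""Grade discrimination: Ward clustering, per-bin ROC, low-dose rule, rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pneumovox as pv
from pneumovox.volumetry import DoseBinFeatures

from .conftest import oracle_ward


def make_features(matrix, grades):
    matrix = np.asarray(matrix, dtype=float)
    pids = [f"P{i}" for i in range(len(matrix))]
    values = pd.DataFrame(matrix, index=pids, columns=range(matrix.shape[1]))
    return DoseBinFeatures(
        values=values,
        grades=dict(zip(pids, grades)),
        missing=pd.DataFrame(np.isnan(matrix), index=pids, columns=range(matrix.shape[1])),
    )


# ------------------------------------------------------------ AUC


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=12),
       st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=12))
def test_auc_equals_normalized_mann_whitney_u(pos, neg):
    x = np.array(pos + neg)
    y = np.array([1] * len(pos) + [0] * len(neg))
    auc, lo, hi = pv.delong_auc_ci(x, y)
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    assert np.isclose(auc, u / (len(pos) * len(neg)), rtol=1e-12)
    assert 0 <= lo <= auc <= hi <= 1


def test_auc_four_point_hand_computation():
    # pos {3, 1}, neg {2, 0}: pairs won = 3 of 4 -> AUC 0.75
    auc, *_ = pv.delong_auc_ci(np.array([3.0, 1.0, 2.0, 0.0]), np.array([1, 1, 0, 0]))
    assert auc == 0.75


def test_disjoint_classes_give_auc_exactly_one():
    X = np.vstack([np.full((4, 11), 0.5), np.full((5, 11), 0.1)])
    X += np.linspace(0, 0.01, 9)[:, None]  # break exact constancy
    feats = make_features(X, [3, 3, 4, 5, 1, 2, 0, 1, 2])
    rep = pv.roc_per_dose_bin(feats)
    assert (rep.per_bin["auc"] == 1.0).all()
    assert (rep.per_bin["lr_p"] < 0.002).all()
    assert not rep.per_bin["coef_finite"].any()  # complete separation flagged


def test_null_features_rarely_significant():
    rng = np.random.default_rng(1)
    hits = 0
    for _ in range(40):
        x = rng.normal(size=(30, 11))
        labels = np.array([1] * 6 + [0] * 24)
        rng.shuffle(labels)
        feats = make_features(x, 3 * labels)
        rep = pv.roc_per_dose_bin(feats, labels)
        hits += int(rep.per_bin["significant"].iloc[0])
    assert hits <= 2
    # and orientation keeps reported AUC >= 0.5
    assert rep.per_bin["auc"].min() >= 0.5


# ------------------------------------------------------------ Ward


def test_ward_linkage_matches_exhaustive_oracle():
    pts = np.array([[0.0], [0.4], [1.1], [5.0], [6.2]])
    feats = make_features(np.repeat(pts, 2, axis=1), [0, 0, 0, 3, 3])
    tree = pv.cluster_cohort(feats, preprocessing="none")
    heights, merges = oracle_ward(np.repeat(pts, 2, axis=1))
    assert np.allclose(np.sort(tree.heights()), np.sort(heights), rtol=1e-12)
    assert tree.bipartition_pure


def test_two_identical_groups_merge_last_with_zero_heights():
    X = np.vstack([np.tile([1.0, 2.0, 3.0], (3, 1)), np.tile([9.0, 8.0, 7.0], (4, 1))])
    feats = make_features(X, [3, 3, 3, 0, 0, 0, 0])
    tree = pv.cluster_cohort(feats, preprocessing="none")
    h = np.sort(tree.heights())
    assert np.allclose(h[:-1], 0.0)
    assert h[-1] > 0
    assert tree.bipartition_pure and tree.bipartition_purity == 1.0


def test_ward_invariant_to_input_order():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 11))
    grades = [3] * 4 + [0] * 8
    t1 = pv.cluster_cohort(make_features(X, grades))
    perm = rng.permutation(12)
    t2 = pv.cluster_cohort(make_features(X[perm], np.array(grades)[perm]))
    assert np.allclose(np.sort(t1.heights()), np.sort(t2.heights()), rtol=1e-9)


def test_constant_features_error_and_missing_imputed():
    feats = make_features(np.ones((4, 11)), [3, 3, 0, 0])
    with pytest.raises(ValueError, match="constant"):
        pv.cluster_cohort(feats)
    X = np.random.default_rng(0).normal(size=(4, 11))
    X[0, 3] = np.nan
    tree = pv.cluster_cohort(make_features(X, [3, 3, 0, 0]))
    assert tree.imputed_missing


def test_newick_export_contains_all_leaves():
    X = np.random.default_rng(2).normal(size=(5, 11))
    tree = pv.cluster_cohort(make_features(X, [3, 0, 0, 0, 0]))
    for pid in tree.patients:
        assert pid in tree.newick
    assert tree.newick.endswith(";")


# ------------------------------------------------------------ rules & tests


def test_low_dose_rule_reports_violators():
    X = np.zeros((3, 11))
    X[0, 0] = 0.4   # high-grade, passes
    X[1, 0] = 0.05  # high-grade, infiltrate-poor -> violator
    X[2, 0] = 0.02  # low-grade
    rep = pv.low_dose_rule(make_features(X, [3, 4, 1]))
    assert not rep["all_pass"] and rep["violators"] == ["P1"]
    assert rep["min_high_grade_pv"] == 0.05


def test_threshold_sweep_matches_manual_counts():
    X = np.zeros((4, 11))
    X[:, 0] = [0.3, 0.2, 0.1, 0.05]
    sweep = pv.discrimination.threshold_sweep(make_features(X, [3, 3, 0, 0]))
    at = lambda t: sweep[np.isclose(sweep["threshold"], t)].iloc[0]  # noqa: E731
    assert at(0.1)["sensitivity"] == 1.0 and at(0.1)["specificity"] == 1.0  # strict >
    assert at(0.05)["sensitivity"] == 1.0 and at(0.05)["specificity"] == 0.5
    assert at(0.2)["sensitivity"] == 0.5 and at(0.2)["specificity"] == 1.0


def test_group_compare_identical_and_shifted():
    same = pv.group_compare([1, 2, 3, 4, 1, 2, 3, 4], [1, 1, 1, 1, 0, 0, 0, 0])
    assert same["p"] > 0.9
    shifted = pv.group_compare(list(range(10)) + list(range(10, 20)),
                               [0] * 10 + [1] * 10)
    assert shifted["test"] == "rank-sum" and shifted["p"] < 0.05
    identical_paired = pv.group_compare([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0],
                                        [1, 1, 1, 1, 0, 0, 0, 0], paired=True)
    assert identical_paired["test"] == "signed-rank" and identical_paired["p"] == 1.0


def test_kruskal_two_groups_equals_ranksum_chi2():
    """For k=2 the Kruskal-Wallis statistic is the squared normal rank-sum z."""
    rng = np.random.default_rng(5)
    a, b = rng.normal(size=8), rng.normal(1.0, 1, 8)
    kw = pv.kruskal_across_bins(np.column_stack([a, b]))
    n1 = n2 = 8
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    z = (r1 - n1 * (n + 1) / 2) / np.sqrt(n1 * n2 * (n + 1) / 12.0)
    assert np.isclose(kw["statistic"], z * z, rtol=1e-10)
    assert kw["df"] == 1


def test_kruskal_identical_bins_is_null():
    M = np.tile([0.3, 0.3, 0.3], (5, 1))
    assert pv.kruskal_across_bins(M)["p"] == 1.0
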