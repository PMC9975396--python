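"""Group statistics, deviation graphs, error maps, and characterization."""

import itertools
import math

import numpy as np
import pytest

from fcnorm.analysis import (
    GroupErrorMatrix,
    binarize_and_degree,
    characterize_group,
    compare_groups,
    group_degree_summary,
    individual_level_matrix,
    merged_threshold,
    mse_per_feature,
    subtract_healthy,
    top_fraction_pairs,
)
from fcnorm.atlas import DEFAULT_ATLAS
from fcnorm.connectivity import devectorize
from fcnorm.model import mse_per_subject


def exact_mannwhitney_p(a, b):
    """Independent oracle: exhaustively enumerate all rank assignments.

    Two-sided p = 2 * min(P(U <= u), P(U >= u)) under the permutation null,
    valid for tie-free samples.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    total = math.comb(n1 + n2, n1)
    count_le = count_ge = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        count_le += u <= u_obs
        count_ge += u >= u_obs
    return min(1.0, 2 * min(count_le, count_ge) / total)


class TestCompareGroups:
    def test_identical_samples_degenerate(self):
        vals = {"a": np.ones(5), "b": np.ones(6)}
        with pytest.warns(UserWarning):
            (cmp,) = compare_groups(vals, [("a", "b")])
        assert cmp.mannwhitney_u == 15.0  # n1*n2/2
        assert cmp.p_value == 1.0

    def test_separated_triplets_exact_p(self):
        vals = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([4.0, 5.0, 6.0])}
        (cmp,) = compare_groups(vals, [("a", "b")])
        assert cmp.method == "exact"
        assert cmp.p_value == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (3, 5), (4, 6), (5, 7), (7, 7)])
    def test_exact_p_matches_enumeration(self, n1, n2, rng):
        for _ in range(3):
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.8, 1, n2)
            (cmp,) = compare_groups({"a": a, "b": b}, [("a", "b")])
            assert cmp.method == "exact"
            assert cmp.p_value == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-12)

    def test_null_calibration(self):
        # rejection rate at alpha = 0.05 under a true null
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
            (cmp,) = compare_groups({"a": a, "b": b}, [("a", "b")])
            rejections += cmp.p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_shapiro_reported_never_gating(self, rng):
        # heavily non-normal data still gets a Mann-Whitney p-value
        a, b = rng.exponential(1, 30) ** 3, rng.exponential(1, 30) ** 3
        (cmp,) = compare_groups({"a": a, "b": b}, [("a", "b")])
        assert 0 <= cmp.shapiro_p_a <= 1
        assert 0 <= cmp.p_value <= 1

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": np.array([1.0, 2.0]), "b": np.ones(5)}, [("a", "b")])


class TestMergedThreshold:
    def test_exact_quintile_on_1_to_10(self):
        vals = np.arange(1.0, 11.0)
        thr = merged_threshold(vals, 0.20)
        retained = vals[vals >= thr]
        assert set(retained) == {9.0, 10.0}

    def test_all_equal_warns_and_retains_everything(self):
        with pytest.warns(UserWarning):
            thr = merged_threshold(np.full(50, 2.5), 0.20)
        assert thr == 2.5

    def test_normal_quantile(self, rng):
        draws = rng.standard_normal(1000)
        assert merged_threshold(draws, 0.20) == pytest.approx(0.8416, abs=0.1)

    def test_monotone_in_fraction(self, rng):
        vals = rng.exponential(1, 500)
        thr_small = merged_threshold(vals, 0.10)
        thr_large = merged_threshold(vals, 0.30)
        assert thr_large <= thr_small
        # raising the retained fraction never drops a retained value
        assert set(np.flatnonzero(vals >= thr_small)) <= set(
            np.flatnonzero(vals >= thr_large)
        )


class TestBinarizedGraphs:
    def test_complete_and_empty_graphs(self):
        g_full = binarize_and_degree(np.ones(91), 0.5)
        assert np.all(g_full.degrees == 13)
        g_empty = binarize_and_degree(np.zeros(91), 0.5)
        assert np.all(g_empty.degrees == 0)

    def test_single_edge(self, atlas):
        vec = np.zeros(91)
        vec[atlas.pair_to_feature("ASN", "BGN")] = 2.0
        g = binarize_and_degree(vec, 1.0)
        expected = np.zeros(14, dtype=int)
        expected[atlas.index("ASN")] = expected[atlas.index("BGN")] = 1
        assert np.array_equal(g.degrees, expected)
        assert np.array_equal(g.adjacency, g.adjacency.T)
        assert np.all(np.diag(g.adjacency) == 0)

    def test_degree_monotone_in_threshold(self, rng):
        vec = rng.exponential(1, 91)
        for lo, hi in [(0.5, 1.0), (1.0, 2.0)]:
            d_lo = binarize_and_degree(vec, lo).degrees
            d_hi = binarize_and_degree(vec, hi).degrees
            assert np.all(d_lo >= d_hi)

    def test_group_medians_and_histogram(self, atlas):
        vecs = [np.zeros(91), np.zeros(91)]
        k = atlas.pair_to_feature("ASN", "BGN")
        vecs[0][k] = 5.0
        vecs[1][:] = 5.0  # complete graph
        graphs = [binarize_and_degree(v, 1.0) for v in vecs]
        medians, hist = group_degree_summary(graphs)
        # ASN/BGN: median of (1, 13) = 7; others: median of (0, 13) = 6.5
        assert medians[atlas.index("ASN")] == 7.0
        assert hist.sum() == 14

    def test_single_subject_medians_equal_degrees(self, rng):
        g = binarize_and_degree(rng.exponential(1, 91), 1.0)
        medians, _ = group_degree_summary([g])
        assert np.array_equal(medians, g.degrees)


class TestErrorMatrices:
    def test_single_subject_squared_residuals(self, rng):
        resid = rng.normal(0, 1, 91)
        mat = mse_per_feature(resid, "g")
        assert np.allclose(mat.feature_values(), resid ** 2)
        assert mat.n_subjects == 1

    def test_opposite_residuals_average_to_one(self):
        resid = np.vstack([np.ones(91), -np.ones(91)])
        mat = mse_per_feature(resid, "g")
        assert np.allclose(mat.feature_values(), 1.0)

    def test_conservation_identity(self, rng):
        resid = rng.normal(0, 1, (25, 91))
        lhs = mse_per_subject(resid).mean()
        rhs = mse_per_feature(resid, "g").feature_values().mean()
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_subtraction(self, rng):
        pa = mse_per_feature(rng.normal(0, 1, (10, 91)), "p")
        he = mse_per_feature(rng.normal(0, 1, (10, 91)), "h")
        diff = subtract_healthy(pa, he)
        assert diff.subtracted
        assert np.allclose(diff.values, pa.values - he.values)
        zero = subtract_healthy(pa, pa)
        assert np.allclose(zero.values, 0.0)
        with pytest.raises(ValueError):
            subtract_healthy(pa, diff)  # already-subtracted baseline

    def test_subtraction_spot_value(self, atlas):
        k = atlas.pair_to_feature("HVN", "RECN")
        a, b = np.zeros(91), np.zeros(91)
        a[k], b[k] = np.sqrt(0.9), np.sqrt(0.4)
        diff = subtract_healthy(
            mse_per_feature(a, "p"), mse_per_feature(b, "h")
        )
        assert diff.at("HVN", "RECN") == pytest.approx(0.5)


class TestTopPairs:
    def test_ten_percent_of_91_is_nine(self, rng):
        mat = mse_per_feature(rng.normal(0, 1, (5, 91)), "g")
        assert len(top_fraction_pairs(mat, 0.10)) == 9

    def test_full_fraction_sorted_descending(self, rng):
        mat = mse_per_feature(rng.normal(0, 1, (5, 91)), "g")
        pairs = top_fraction_pairs(mat, 1.0)
        values = [v for _, v in pairs]
        assert len(pairs) == 91
        assert values == sorted(values, reverse=True)

    def test_unique_maximum_ranked_first(self, atlas):
        vec = np.zeros(91)
        vec[atlas.pair_to_feature("HVN", "RECN")] = 9.0
        mat = mse_per_feature(vec, "g")
        (top_pair, top_val), *_ = top_fraction_pairs(mat, 0.10)
        assert set(top_pair) == {"HVN", "RECN"}
        assert top_val == pytest.approx(81.0)

    def test_tie_break_by_ascending_feature_index(self):
        mat = mse_per_feature(np.ones(91), "g")  # all values tied
        pairs = top_fraction_pairs(mat, 0.10)
        indices = [DEFAULT_ATLAS.pair_to_feature(*p) for p, _ in pairs]
        assert indices == list(range(9))


class TestCharacterization:
    def _sets(self, a_before, a_after, b_before, b_after):
        return {
            "a": {"before": a_before, "after": a_after},
            "b": {"before": b_before, "after": b_after},
        }

    def test_rule_1_pair_in_all_four_sets(self):
        p = ("ASN", "BGN")
        res = characterize_group("g", self._sets([p], [p], [p], [p]))
        assert res.rule_1 == frozenset({p})
        assert res.rule_3 == frozenset()

    def test_rule_3_pair_after_only(self):
        p = ("BGN", "HVN")
        other = ("ASN", "AN")
        res = characterize_group(
            "g", self._sets([other], [p], [other], [p])
        )
        assert res.rule_3 == frozenset({p})
        assert p in res.characteristic

    def test_rule_2_pair_before_only_excluded(self):
        p = ("LN", "SN")
        res = characterize_group(
            "g", self._sets([p], [("ASN", "AN")], [p], [("ASN", "AN")])
        )
        assert p in res.rule_2
        assert p not in res.characteristic

    def test_condition_must_agree(self):
        # present after subtraction in (a) only: not characteristic
        p = ("BGN", "HVN")
        res = characterize_group(
            "g", self._sets([], [p], [], [])
        )
        assert res.characteristic == frozenset()

    def test_rules_disjoint_and_orientation_canonicalized(self):
        p_rev = ("BGN", "ASN")  # reversed orientation of the same pair
        res = characterize_group(
            "g", self._sets([("ASN", "BGN")], [p_rev], [p_rev], [("ASN", "BGN")])
        )
        assert res.rule_1 & res.rule_3 == frozenset()
        assert len(res.rule_1) == 1

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError):
            characterize_group("g", {"a": {"before": [], "after": []}})


class TestIndividualLevel:
    def test_perfect_subject_zero_row(self, atlas):
        pairs = [("ASN", "BGN"), ("BGN", "HVN")]
        subj = {"h": np.zeros(91), "p": np.ones(91)}
        mat, ids, flags = individual_level_matrix(pairs, subj, ["h"])
        assert np.all(mat[ids.index("h")] == 0.0)
        assert flags[ids.index("p")]

    def test_single_pair_single_subject(self, atlas):
        vec = np.zeros(91)
        vec[atlas.pair_to_feature("LN", "SN")] = 0.7
        mat, ids, _ = individual_level_matrix([("LN", "SN")], {"s": vec})
        assert mat.shape == (1, 1)
        assert mat[0, 0] == pytest.approx(0.7)

    def test_heterogeneity_exists_in_synthetic_cohort(self, small_report):
        mat, ids, flags = small_report.individual["SCZ-Test-U"]
        assert mat.shape[0] == 30  # 15 healthy + 15 patients
        assert mat.var(axis=1).max() > 0

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError):
            individual_level_matrix([], {"s": np.zeros(91)})
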