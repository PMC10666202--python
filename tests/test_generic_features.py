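from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from conftest import make_pair
from etpred.generic_features import (
    CrossCTPanel,
    PanelMatrix,
    activity_split,
    aggregate_overlaps,
    combined_tests_feature,
    crup_correlation,
    fisher_combine,
    genomic_distance,
    rank_sum_test,
)
from etpred.genome_io import GenomicRegion


def mannwhitney_p_oracle(x, y):
    """Exhaustive permutation p-value via the U statistic (pairwise wins)."""

    def u_stat(a, b):
        return sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)

    pooled = list(x) + list(y)
    observed = u_stat(x, y)
    hits = total = 0
    for idx in combinations(range(len(pooled)), len(x)):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        hits += u_stat(a, b) >= observed - 1e-9
    return hits / total


class TestActivitySplit:
    def test_tpm_positive_rule(self):
        np.testing.assert_array_equal(
            activity_split([0, 3.2, 0, 0.1], "tpm_positive"),
            [False, True, False, True],
        )

    def test_top_quantile_selects_ceil_quarter(self):
        values = [5, 1, 7, 3, 8, 2, 6, 4]  # 8 distinct -> exactly 2 active
        mask = activity_split(values, "top_quantile_0.25")
        assert mask.sum() == 2
        assert list(np.flatnonzero(mask)) == [2, 4]  # the two largest

    def test_top_quantile_breaks_ties_by_index(self):
        mask = activity_split([1.0, 1.0, 1.0, 1.0, 1.0], "top_quantile_0.25")
        assert list(np.flatnonzero(mask)) == [0, 1]  # ceil(1.25) = 2, earliest win

    def test_all_zero_vector_is_all_inactive_under_tpm_rule(self):
        assert not activity_split(np.zeros(6), "tpm_positive").any()

    def test_mean_ep_rule_is_strict(self):
        np.testing.assert_array_equal(
            activity_split([0.5, 0.51, 0.2], "mean_ep_gt_0.5"),
            [False, True, False],
        )

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="rule"):
            activity_split([1.0], "median")


class TestRankSum:
    def test_fully_separated_groups(self):
        target = np.array([10, 11, 12, 1, 2, 3], float)
        mask = np.array([True, True, True, False, False, False])
        assert rank_sum_test(target, mask) == pytest.approx(0.05)

    def test_empty_group_gives_one(self):
        assert rank_sum_test(np.array([1.0, 2.0]), np.array([True, True])) == 1.0
        assert rank_sum_test(np.array([1.0, 2.0]), np.array([False, False])) == 1.0

    def test_identical_multisets_not_significant(self):
        target = np.array([1, 2, 3, 1, 2, 3], float)
        mask = np.array([True, True, True, False, False, False])
        assert rank_sum_test(target, mask) >= 0.5

    def test_exact_path_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n1, n2 = rng.integers(2, 6, size=2)
            target = rng.choice([0.0, 1.0, 2.0, 3.5, 7.0], size=n1 + n2)
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[:n1] = True
            expected = mannwhitney_p_oracle(target[:n1], target[n1:])
            assert rank_sum_test(target, mask) == pytest.approx(expected, abs=1e-12)

    def test_asymptotic_path_close_to_exact_enumeration(self):
        rng = np.random.default_rng(1)
        target = rng.normal(size=18)
        target[:9] += 1.0
        mask = np.zeros(18, dtype=bool)
        mask[:9] = True
        approx = rank_sum_test(target, mask)  # 9 > exact cutoff
        exact = mannwhitney_p_oracle(target[:9], target[9:])
        assert approx == pytest.approx(exact, abs=0.01)


class TestAggregateOverlaps:
    element = GenomicRegion("chr1", 1000, 1300, "E")

    def test_sums_overlapping_peak_values(self):
        peaks = [
            (GenomicRegion("chr1", 900, 1100), 2.0),
            (GenomicRegion("chr1", 1250, 1400), 3.5),
            (GenomicRegion("chr1", 5000, 5100), 100.0),
        ]
        assert aggregate_overlaps(self.element, peaks) == 5.5

    def test_no_overlap_gives_zero(self):
        assert aggregate_overlaps(self.element, []) == 0.0

    def test_abutting_peak_not_counted(self):
        peaks = [(GenomicRegion("chr1", 800, 1000), 9.0),
                 (GenomicRegion("chr1", 1300, 1500), 9.0)]
        assert aggregate_overlaps(self.element, peaks) == 0.0

    def test_other_chromosome_not_counted(self):
        peaks = [(GenomicRegion("chr2", 1000, 1300), 9.0)]
        assert aggregate_overlaps(self.element, peaks) == 0.0


class TestFisherCombination:
    def test_all_ones_combine_to_one(self):
        res = fisher_combine([1, 1, 1, 1])
        assert res.combined_p == pytest.approx(1.0)
        assert res.neg_log_p == pytest.approx(0.0)

    def test_four_nominal_pvalues_match_chi_square_oracle(self):
        res = fisher_combine([0.05] * 4)
        statistic = -2 * 4 * np.log(0.05)
        assert res.statistic == pytest.approx(statistic, abs=1e-6)  # ~23.966
        assert res.df == 8
        assert res.combined_p == pytest.approx(stats.chi2.sf(statistic, 8))
        assert res.combined_p == pytest.approx(0.0023, abs=2e-4)

    def test_three_available_tests_use_six_degrees_of_freedom(self):
        assert fisher_combine([0.2, 0.3, 0.4]).df == 6

    @given(st.floats(1e-10, 1.0))
    def test_single_pvalue_identity(self, p):
        assert fisher_combine([p]).combined_p == pytest.approx(p, rel=1e-9)

    def test_zero_pvalue_clamped_to_finite_log(self):
        res = fisher_combine([0.0, 0.5])
        assert np.isfinite(res.neg_log_p) and res.neg_log_p > 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])

    def test_combined_uniform_pvalues_stay_uniform(self):
        rng = np.random.default_rng(0)
        draws = rng.random((10_000, 4))
        combined = np.array([fisher_combine(row).combined_p for row in draws])
        assert stats.kstest(combined, "uniform").pvalue > 0.01


class TestCrupCorrelation:
    def test_perfectly_linear_vectors(self):
        assert crup_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert crup_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_vector_gives_zero(self):
        assert crup_correlation([2, 2, 2], [1, 5, 9]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crup_correlation([1, 2], [1, 2, 3])

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(2)
        e, g = rng.random(30), rng.random(30)
        base = crup_correlation(e, g)
        assert crup_correlation(3.5 * e + 2, g) == pytest.approx(base)
        assert crup_correlation(e, 0.1 * g + 7) == pytest.approx(base)


class TestGenomicDistance:
    @pytest.mark.parametrize(
        "enh_mid,tss_pos,expected",
        [(1150, 2150, 1000), (2150, 2150, 0), (3150, 2150, 1000)],
    )
    def test_absolute_midpoint_to_tss(self, enh_mid, tss_pos, expected):
        assert genomic_distance(make_pair(enh_mid=enh_mid, tss_pos=tss_pos)) == expected


def _panel(kind, enh_rows, target_rows, rule=""):
    biosamples = [f"B{i}" for i in range(len(next(iter(enh_rows.values()))))]
    return PanelMatrix(
        kind,
        pd.DataFrame.from_dict(enh_rows, orient="index", columns=biosamples),
        pd.DataFrame.from_dict(target_rows, orient="index", columns=biosamples),
        activity_rule=rule,
    )


class TestPanels:
    def test_unmeasured_element_returns_none(self):
        panel = _panel("CAGE", {"E1": [0, 1, 2, 0]}, {"G1": [1, 2, 3, 4]})
        assert panel.pair_pvalue("E2", "G1") is None
        assert panel.pair_pvalue("E1", "G9") is None
        assert panel.pair_pvalue("E1", "G1") is not None

    def test_all_zero_row_is_a_measurement_not_missing(self):
        panel = _panel("CAGE", {"E1": [0, 0, 0, 0]}, {"G1": [1, 2, 3, 4]})
        assert panel.pair_pvalue("E1", "G1") == 1.0  # empty active group

    def test_combined_feature_shrinks_with_missing_panels(self):
        rng = np.random.default_rng(3)
        enh = {"E1": rng.random(12) + 0.1}
        target = {"G1": rng.random(12)}
        covered = [_panel(k, enh, target) for k in ("CAGE", "DHS", "DHS_EXPR")]
        absent = _panel("CRUP_EXPR", {"EX": rng.random(12)}, target)
        pvals = [p.pair_pvalue("E1", "G1") for p in covered]
        expected = fisher_combine(pvals).neg_log_p
        got = combined_tests_feature(covered + [absent], "E1", "G1")
        assert got == pytest.approx(expected)
        assert fisher_combine(pvals).df == 6

    def test_pair_in_no_panel_scores_zero(self):
        panel = _panel("CAGE", {"E1": [0, 1.0]}, {"G1": [1.0, 2.0]})
        assert combined_tests_feature([panel], "EX", "GX") == 0.0

    def test_mismatched_biosample_axes_rejected(self):
        with pytest.raises(ValueError, match="biosample"):
            PanelMatrix(
                "CAGE",
                pd.DataFrame([[1.0]], index=["E1"], columns=["B1"]),
                pd.DataFrame([[1.0]], index=["G1"], columns=["B2"]),
            )


class TestCrossCTPanel:
    def test_pair_correlation_and_missing_default(self):
        ct = [f"C{i}" for i in range(3)]
        panel = CrossCTPanel(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["E1"], columns=ct),
            pd.DataFrame([[2.0, 4.0, 6.0]], index=["G1"], columns=ct),
        )
        assert panel.pair_correlation("E1", "G1") == pytest.approx(1.0)
        assert panel.pair_correlation("E9", "G1") == 0.0
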