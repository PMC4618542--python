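"""Hypothesis-test toolkit: chi-square, Mann-Whitney, Spearman, OLS trend."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mrruf.stats import (
    chi_square_homogeneity,
    mann_whitney_u,
    ols_trend,
    pairwise_vs_reference,
    spearman_rho,
)


class TestChiSquare:
    def test_hand_computed_two_by_two(self):
        # O = [[10,90],[30,70]]; E = [[20,80],[20,80]] -> sum (O-E)^2/E = 12.5
        result = chi_square_homogeneity([[10, 90], [30, 70]])
        assert result.statistic == pytest.approx(12.5)
        assert "df=1" in result.method_notes

    def test_identical_rows_give_zero(self):
        result = chi_square_homogeneity([[25, 75], [25, 75]])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", [[[0, 0], [5, 5]], [[5, 0], [5, 0]], [[5, 5], [-1, 5]]]
    )
    def test_degenerate_tables_raise(self, table):
        with pytest.raises(ValueError):
            chi_square_homogeneity(table)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    def test_two_by_two_equals_squared_z(self, a, b, c, d):
        """Pearson chi-square on a 2x2 table equals the squared pooled
        two-proportion z statistic."""
        chi2 = chi_square_homogeneity([[a, b], [c, d]]).statistic
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        p_pool = (a + c) / (n1 + n2)
        if p_pool in (0.0, 1.0):
            return
        z = (p1 - p2) / math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        assert chi2 == pytest.approx(z * z, rel=1e-10)


class TestPairwiseVsReference:
    COUNTS = {"<1": (100, 900), "1": (100, 900), "2-4": (20, 980)}

    def test_identical_group_is_not_flagged(self):
        results = {
            r.group: r
            for r in pairwise_vs_reference(self.COUNTS, "<1")
        }
        assert results["1"].p_value == pytest.approx(1.0)
        assert results["1"].significant is False
        assert results["2-4"].significant is True

    def test_bonferroni_multiplies_raw_p(self):
        raw = {
            r.group: r.p_value
            for r in pairwise_vs_reference(self.COUNTS, "<1", correction="none")
        }
        corrected = {
            r.group: r.p_value
            for r in pairwise_vs_reference(self.COUNTS, "<1")
        }
        for g in raw:
            assert corrected[g] == pytest.approx(min(1.0, raw[g] * 2))

    def test_borderline_raw_p_loses_significance_after_correction(self):
        # two comparisons with raw p ~ 0.03 are corrected to ~ 0.06
        counts = {"ref": (50, 950), "g1": (73, 927), "g2": (73, 927)}
        raw = pairwise_vs_reference(counts, "ref", correction="none")
        assert all(0.01 < r.p_value < 0.05 for r in raw)
        corr = pairwise_vs_reference(counts, "ref", correction="bonferroni")
        for r_raw, r_corr in zip(raw, corr):
            assert r_corr.p_value == pytest.approx(min(1.0, 2 * r_raw.p_value))
            assert r_corr.significant is (r_corr.p_value < 0.05)

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            pairwise_vs_reference(self.COUNTS, "absent")


def _brute_force_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the combined observations to the first sample."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    nx = len(x)
    obs = ranks[:nx].sum()
    sums = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(combined)), nx)
    ]
    total = len(sums)
    lower = sum(s <= obs + 1e-9 for s in sums)
    upper = sum(s >= obs - 1e-9 for s in sums)
    return min(1.0, 2 * min(lower, upper) / total)


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        result = mann_whitney_u([1, 2], [3, 4], mode="exact")
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        result = mann_whitney_u([1, 2, 3], [1, 2, 3], mode="exact")
        assert result.p_value == pytest.approx(1.0)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_all_values_tied_is_degenerate(self):
        result = mann_whitney_u([5, 5], [5, 5, 5], mode="normal")
        assert result.p_value == 1.0

    @settings(max_examples=60, deadline=None)
    @given(
        x=st.lists(st.integers(0, 6), min_size=1, max_size=6),
        y=st.lists(st.integers(0, 6), min_size=1, max_size=6),
    )
    def test_exact_p_matches_enumeration_with_ties(self, x, y):
        """DP over the permutation null reproduces brute-force
        enumeration, including heavy ties."""
        result = mann_whitney_u(x, y, mode="exact")
        assert result.p_value == pytest.approx(
            _brute_force_mw_p(np.array(x, float), np.array(y, float))
        )

    def test_u_statistic_matches_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=15), rng.normal(0.5, size=18)
        ours = mann_whitney_u(x, y, mode="normal")
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_and_normal_agree_near_switch_boundary(self, seed):
        # n_x * n_y = 400, the largest exact case
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(0.3, size=20)
        p_exact = mann_whitney_u(x, y, mode="exact").p_value
        p_norm = mann_whitney_u(x, y, mode="normal").p_value
        assert abs(p_exact - p_norm) <= 0.02

    def test_auto_mode_switches_on_sample_product(self):
        small = mann_whitney_u([1, 2], [3, 4])
        assert "exact" in small.method_notes
        big = mann_whitney_u(np.arange(30), np.arange(30) + 0.5)
        assert "normal" in big.method_notes

    @settings(max_examples=30, deadline=None)
    @given(
        x=st.lists(st.integers(1, 50), min_size=2, max_size=8),
        y=st.lists(st.integers(1, 50), min_size=2, max_size=8),
    )
    def test_invariant_to_monotone_transformation(self, x, y):
        # integer grid keeps the tie structure exact under the transform
        x, y = np.array(x, float), np.array(y, float)
        a = mann_whitney_u(x, y, mode="exact")
        b = mann_whitney_u(np.log(x), np.log(y), mode="exact")
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)


class TestSpearman:
    def test_monotone_increasing_gives_one(self):
        result = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert result.statistic == pytest.approx(1.0)

    def test_hand_example(self):
        # d = (2, 1, 1) -> sum d^2 = 6 -> rho = 1 - 36/24 = -0.5
        result = spearman_rho([1, 2, 3], [3, 1, 2])
        assert result.statistic == pytest.approx(-0.5)

    def test_constant_input_undefined(self):
        result = spearman_rho([1, 1, 1], [1, 2, 3])
        assert math.isnan(result.statistic)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])

    def test_midranks_match_pearson_on_ranks_oracle(self):
        # n = 4 with one tie pair
        x = [1.0, 2.0, 2.0, 5.0]
        y = [3.0, 1.0, 4.0, 2.0]
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y).statistic == pytest.approx(oracle)

    @pytest.mark.parametrize("seed", range(4))
    def test_rho_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        ours = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=0.05)

    def test_exact_permutation_p_small_n(self):
        # perfectly concordant n=4: only 2 of 24 orderings reach |rho|=1
        result = spearman_rho([1, 2, 3, 4], [1, 2, 3, 4], mode="auto")
        assert "permutation" in result.method_notes
        assert result.p_value == pytest.approx(2 / 24)


class TestOlsTrend:
    def test_exact_linear_fit(self):
        fit = ols_trend([0, 1, 2, 3], [1, 3, 5, 7])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.adjusted_r_squared == pytest.approx(1.0)

    def test_symmetric_tent_has_zero_slope(self):
        fit = ols_trend([0, 1, 2], [0, 1, 0])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_adjusted_r_squared_formula(self):
        rng = np.random.default_rng(0)
        x = np.arange(20.0)
        y = 0.5 * x + rng.normal(size=20)
        fit = ols_trend(x, y)
        n = 20
        expected = 1 - (1 - fit.r_squared) * (n - 1) / (n - 2)
        assert fit.adjusted_r_squared == pytest.approx(expected)
        assert fit.adjusted_r_squared <= fit.r_squared <= 1.0

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            ols_trend([2, 2, 2], [1, 2, 3])
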