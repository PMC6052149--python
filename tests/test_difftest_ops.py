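"""Component statistics, permutation machinery, Stouffer and Storey ops."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from vocdiff import (
    PermutationConfig,
    fold_change_sd,
    log2_median_ratio,
    permutation_pvalue,
    storey_qvalues,
    stouffer_combine,
    t_statistic,
    wilcoxon_ranksum_p,
)


class TestTStatistic:
    def test_identical_groups_give_zero(self):
        assert t_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_welch_value(self):
        # mean diff 4, se = sqrt(1/3 + 1/3)
        expected = 4.0 / math.sqrt(2.0 / 3.0)
        assert t_statistic([5, 6, 7], [1, 2, 3]) == pytest.approx(expected, abs=1e-12)
        assert t_statistic([5, 6, 7], [1, 2, 3]) == pytest.approx(4.899, abs=1e-3)

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        assert t_statistic(a, b) == pytest.approx(-t_statistic(b, a), rel=1e-9, abs=1e-12)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 7), rng.normal(0.5, 2, 9)
        expected = stats.ttest_ind(a, b, equal_var=False).statistic
        assert t_statistic(a, b) == pytest.approx(expected, rel=1e-12)


class TestLog2MedianRatio:
    def test_examples(self):
        assert log2_median_ratio([4, 4, 4], [1, 1, 1]) == pytest.approx(2.0)
        assert log2_median_ratio([3, 1, 2], [3, 1, 2]) == 0.0
        assert log2_median_ratio([2, 8], [4, 4]) == pytest.approx(math.log2(5 / 4))

    def test_nonpositive_median_flagged_untestable(self):
        from vocdiff.difftest import UntestableFeature

        with pytest.raises(UntestableFeature):
            log2_median_ratio([-1.0, -2.0, -3.0], [1.0, 2.0, 3.0])


class TestFoldChangeSd:
    def test_quarter_fold_is_minus_two(self):
        fc, _ = fold_change_sd([1.0, 1.0], [4.0, 4.0])
        assert fc == pytest.approx(-2.0)

    def test_constant_equal_groups(self):
        fc, sd = fold_change_sd([2.0, 2.0], [2.0, 2.0])
        assert fc == 0.0 and sd == 0.0

    def test_pooled_sd_hand_computation(self):
        # case log2 values {0, 2}, control {1, 3}: pooled sd = sqrt(2)
        fc, sd = fold_change_sd([1.0, 4.0], [2.0, 8.0])
        assert sd == pytest.approx(math.sqrt(2.0), abs=1e-12)


class TestPermutationPvalue:
    def test_exhaustive_mean_diff_enumeration(self):
        config = PermutationConfig(n_permutations=100, seed=0, exhaustive_threshold=50)
        p = permutation_pvalue(
            [1, 2, 3, 4, 5, 6], ["A"] * 3 + ["B"] * 3, "mean_diff", config
        )
        assert p == pytest.approx(2 / 20)

    def test_exhaustive_matches_independent_enumeration(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, 8)
        labels = np.array(["A"] * 4 + ["B"] * 4)
        config = PermutationConfig(n_permutations=100, seed=1, exhaustive_threshold=100)
        p = permutation_pvalue(values, labels, "t", config)
        # brute-force oracle over all C(8,4) assignments
        obs = abs(t_statistic(values[:4], values[4:]))
        count = total = 0
        for case_idx in itertools.combinations(range(8), 4):
            case = values[list(case_idx)]
            ctrl = values[[i for i in range(8) if i not in case_idx]]
            count += abs(t_statistic(case, ctrl)) >= obs
            total += 1
        assert p == pytest.approx(count / total)

    def test_zero_statistic_gives_p_one(self):
        config = PermutationConfig(n_permutations=200, seed=0, exhaustive_threshold=1000)
        p = permutation_pvalue(
            [1, 2, 3, 3, 2, 1], ["A"] * 3 + ["B"] * 3, "mean_diff", config
        )
        assert p == 1.0

    def test_constant_data_gives_p_one(self):
        config = PermutationConfig(n_permutations=200, seed=0)
        assert permutation_pvalue([5.0] * 8, ["A"] * 4 + ["B"] * 4, "t", config) == 1.0

    def test_same_seed_reproducible_sampled(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, 16)
        labels = ["A"] * 8 + ["B"] * 8
        config = PermutationConfig(n_permutations=500, seed=42, exhaustive_threshold=10)
        p1 = permutation_pvalue(values, labels, "t", config)
        p2 = permutation_pvalue(values, labels, "t", config)
        assert p1 == p2
        assert p1 >= 1 / 501  # add-one rule: never zero

    def test_callable_statistic_agrees_with_builtin(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, 8)
        labels = ["A"] * 4 + ["B"] * 4
        config = PermutationConfig(n_permutations=100, seed=3, exhaustive_threshold=100)
        p_builtin = permutation_pvalue(values, labels, "t", config)
        p_callable = permutation_pvalue(values, labels, t_statistic, config)
        assert p_builtin == p_callable

    def test_sampled_converges_to_exhaustive(self):
        rng = np.random.default_rng(8)
        values = np.exp(rng.normal(0, 1, 10))
        labels = ["A"] * 5 + ["B"] * 5
        exact = permutation_pvalue(
            values, labels, "t", PermutationConfig(n_permutations=100, seed=0)
        )  # C(10,5)=252 -> exhaustive under the default threshold
        sampled = permutation_pvalue(
            values, labels, "t",
            PermutationConfig(n_permutations=5000, seed=1, exhaustive_threshold=10),
        )
        assert sampled == pytest.approx(exact, abs=0.02)


class TestWilcoxon:
    def test_separated_groups_exact_p(self):
        assert wilcoxon_ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_all_tied_values_give_p_one(self):
        assert wilcoxon_ranksum_p([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            pooled = rng.normal(0, 1, 10)
            case, ctrl = pooled[:5], pooled[5:]
            p = wilcoxon_ranksum_p(case, ctrl)
            ranks = stats.rankdata(pooled)
            mu = 5 * 11 / 2
            obs = abs(ranks[:5].sum() - mu)
            count = total = 0
            for case_idx in itertools.combinations(range(10), 5):
                count += abs(ranks[list(case_idx)].sum() - mu) >= obs
                total += 1
            assert p == pytest.approx(count / total, abs=1e-12)

    def test_exact_and_asymptotic_paths_agree(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            case, ctrl = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
            exact = wilcoxon_ranksum_p(case, ctrl)
            approx = wilcoxon_ranksum_p(case, ctrl, exhaustive_threshold=1)
            assert approx == pytest.approx(exact, abs=0.02)


class TestStoufferCombine:
    def test_all_null_pvalues(self):
        z, p = stouffer_combine(1.0, 1.0, 1.0, 1)
        assert z == 0.0 and p == 1.0

    def test_concordant_0p05(self):
        z, p = stouffer_combine(0.05, 0.05, 0.05, 1)
        assert z == pytest.approx(1.95996 * math.sqrt(3), abs=1e-4)
        assert p == pytest.approx(6.87e-4, rel=1e-2)

    def test_one_discordant_direction(self):
        z, p = stouffer_combine(0.05, 0.05, 0.05, [1, 1, -1])
        assert abs(z) == pytest.approx(1.95996 / math.sqrt(3), abs=1e-4)
        assert p == pytest.approx(0.2578, abs=1e-4)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            z, p = stouffer_combine(0.0, 0.5, 0.5, 1)
        assert np.isfinite(z) and 0 < p <= 1


class TestStoreyQvalues:
    def test_hand_computed_example(self):
        q = storey_qvalues([0.2, 0.4, 0.6, 0.8])
        np.testing.assert_allclose(q, [0.8, 0.8, 0.8, 0.8])

    def test_single_pvalue_reduces_to_itself(self):
        np.testing.assert_allclose(storey_qvalues([0.04]), [0.04])

    def test_matches_bh_when_pi0_is_one(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.001, 1.0, 200)
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.001, 1.0, 100)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all((q > 0) & (q <= 1))

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            storey_qvalues([])
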