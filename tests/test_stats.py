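"""RPKM/CPM identities, count test, BH, Wilcoxon, Cohen's d, comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from chlamirna import stats
from chlamirna.stats import (
    benjamini_hochberg,
    bin_expression_histogram,
    classify_expression,
    cohens_d,
    compare_expression_vs_targets,
    compute_rpkm,
    count_test,
    de_flag,
    wilcoxon_rank_sum,
)


class TestRpkm:
    @pytest.mark.parametrize(
        "c,n,length,expected",
        [(1000, 10**7, 1000, 100.0), (0, 100, 50, 0.0), (5, 10**6, 2000, 2.5)],
    )
    def test_formula(self, c, n, length, expected):
        assert compute_rpkm(c, n, length) == pytest.approx(expected)

    def test_scale_invariance_in_depth(self, rng):
        for _ in range(20):
            c = int(rng.integers(1, 1000))
            n = int(rng.integers(10**5, 10**7))
            length = int(rng.integers(200, 5000))
            assert compute_rpkm(2 * c, 2 * n, length) == pytest.approx(
                compute_rpkm(c, n, length)
            )

    @pytest.mark.parametrize("kwargs", [dict(c=1, n=0, length=10), dict(c=1, n=10, length=0)])
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            compute_rpkm(**kwargs)


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        # p*(n/rank) = (.04, .04, .04, .04) after the step-up minimum
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_sorted_p(self, rng):
        p = rng.random(50)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all() and (q >= p - 1e-12).all()


class TestDeFlag:
    def test_fold_change_and_flag(self):
        result = de_flag([10.0, 10.0], [40.0, 15.0], [0.001, 0.001])
        assert result.loc[0, "log2_fc"] == pytest.approx(2.0)
        assert bool(result.loc[0, "is_de"])
        # 1.5-fold change stays below the 2-fold rule despite tiny q
        assert not result.loc[1, "is_de"]

    def test_pseudo_rpkm_applied_on_zeros(self):
        result = de_flag([0.0], [0.9], [0.5])
        assert result.loc[0, "log2_fc"] == pytest.approx(math.log2(1.0 / 0.1))

    def test_q_threshold(self):
        result = de_flag([10.0], [80.0], [0.2])
        assert not result.loc[0, "is_de"]  # q too large


class TestCountTest:
    def test_symmetric_null_is_one(self):
        assert count_test(7, 1000, 7, 1000) == pytest.approx(1.0)

    def test_exact_tail_example(self):
        # all 10 counts on one side with equal library sizes: 2 * (1/2)^10
        assert count_test(0, 1000, 10, 1000) == pytest.approx(2 * 0.5**10)

    def test_matches_exhaustive_enumeration(self, rng):
        # sum binomial pmf over outcomes no more probable than observed
        from scipy.stats import binom

        for _ in range(25):
            n1 = int(rng.integers(500, 2000))
            n2 = int(rng.integers(500, 2000))
            total = int(rng.integers(1, 20))
            c1 = int(rng.integers(0, total + 1))
            p0 = n1 / (n1 + n2)
            pmf = binom.pmf(np.arange(total + 1), total, p0)
            expected = pmf[pmf <= pmf[c1] * (1 + 1e-9)].sum()
            assert count_test(c1, n1, total - c1, n2) == pytest.approx(expected)

    def test_zero_counts(self):
        assert count_test(0, 100, 0, 100) == 1.0


class TestHistogramAndClass:
    def test_boundary_goes_right(self):
        counts = bin_expression_histogram([0, 499, 500, 1200])
        assert counts.tolist() == [2, 1, 1]

    def test_empty_input(self):
        assert bin_expression_histogram([]).size == 0

    def test_counts_conserved(self, rng):
        values = rng.random(200) * 5000
        assert bin_expression_histogram(values).sum() == 200

    @pytest.mark.parametrize(
        "cpm,expected", [(499.9, "low"), (500.0, "high"), (0.0, "low"), (10_000, "high")]
    )
    def test_expression_class_cutoff_inclusive(self, cpm, expected):
        assert classify_expression(cpm) == expected


def exhaustive_rank_sum_p(a, b):
    """Two-sided p from the full permutation distribution of the rank sum."""
    pooled = sorted(a + b)
    n = len(a)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}  # distinct values only
    observed = sum(ranks[v] for v in a)
    mean = n * (len(pooled) + 1) / 2
    stat = abs(observed - mean)
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        total += 1
        if abs(sum(combo) - mean) >= stat - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_textbook_example(self):
        _u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_central(self):
        _u, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_constant_data_returns_one(self):
        _u, p = wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_matches_permutation_distribution(self, rng):
        for n in (2, 3, 4, 5):
            values = list(rng.permutation(np.arange(1, 2 * n + 1, dtype=float)))
            a, b = values[:n], values[n:]
            _u, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(exhaustive_rank_sum_p(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # pooled SD = sqrt(4/3); |d| = 1 / sqrt(4/3) = 0.866
        assert abs(cohens_d([0, 0, 2, 2], [1, 1, 3, 3])) == pytest.approx(
            0.866, abs=1e-3
        )

    def test_scale_invariance(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(loc=1.0, size=12)
        assert cohens_d(3.7 * a, 3.7 * b) == pytest.approx(cohens_d(a, b))

    def test_sign_convention_first_minus_second(self):
        assert cohens_d([5.0, 6.0], [1.0, 2.0]) > 0

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([2, 2], [3, 3])


def make_tables(low_counts, high_counts):
    expression = pd.DataFrame(
        {
            "mirna_id": [f"m{i}" for i in range(len(low_counts) + len(high_counts))],
            "mean_cpm": [100.0] * len(low_counts) + [900.0] * len(high_counts),
        }
    )
    counts = pd.DataFrame(
        {
            "mirna": expression["mirna_id"],
            "cleavage": list(low_counts) + list(high_counts),
            "translational": 1,
            "excluded": False,
        }
    )
    return expression, counts


class TestCompareExpressionVsTargets:
    def test_group_assembly_and_stats(self):
        expression, counts = make_tables([5, 6, 7, 8], [1, 2, 1, 2])
        comparison = compare_expression_vs_targets(expression, counts, "cleavage")
        assert comparison.n_low == 4 and comparison.n_high == 4
        assert comparison.mean_low == pytest.approx(6.5)
        assert comparison.mean_high == pytest.approx(1.5)
        assert comparison.cohens_d > 0
        assert 0 < comparison.p_two_sided < 0.05

    def test_no_target_mirnas_excluded(self):
        expression, counts = make_tables([5, 6, 7], [1, 2])
        counts.loc[0, ["cleavage", "translational"]] = 0
        comparison = compare_expression_vs_targets(expression, counts, "cleavage")
        assert comparison.n_low == 2
        assert comparison.mean_low == pytest.approx(6.5)

    def test_all_excluded_raises(self):
        expression, counts = make_tables([5], [1])
        counts["excluded"] = True
        with pytest.raises(ValueError):
            compare_expression_vs_targets(expression, counts, "cleavage")

    def test_p_decreases_with_planted_effect(self):
        from chlamirna.synthetic import simulate_target_counts

        pvalues = []
        for mean_low in (2.0, 4.0, 8.0):
            ps = []
            for seed in range(8):
                low, high = simulate_target_counts(
                    mean_low=mean_low, mean_high=1.78, rng_seed=seed
                )
                ps.append(wilcoxon_rank_sum(low, high)[1])
            pvalues.append(np.median(ps))
        assert pvalues[0] > pvalues[2]
        assert pvalues[1] > pvalues[2] or pvalues[0] > pvalues[1]
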