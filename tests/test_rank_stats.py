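"""Unit tests for win probabilities, their plug-ins, and the statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twophase_npt import (
    DegenerateStatisticError,
    InputError,
    group_by_genotype,
    kruskal_wallis,
    max3,
    npt_statistic,
    win_prob,
    win_prob_cov,
    win_prob_estimates,
    win_prob_variance,
    z1_statistic,
)
from twophase_npt.rank_stats import GroupedTrait, _pair_fractions


# --- independent oracles (brute-force double loops) -------------------------


def brute_win_prob(a, b, ties="strict"):
    total = 0.0
    for x in a:
        for y in b:
            if x < y:
                total += 1.0
            elif ties == "midrank" and x == y:
                total += 0.5
    return total / (len(a) * len(b))


def brute_variance(a, b):
    na, nb = len(a), len(b)
    p = [np.mean([x < y for y in b]) for x in a]
    q = [np.mean([x < y for x in a]) for y in b]
    return (
        (nb - 1) / (na**2 * nb) * sum((v - 0.5) ** 2 for v in p)
        + (na - 1) / (na * nb**2) * sum((v - 0.5) ** 2 for v in q)
        + 1 / (4 * na * nb)
    )


def brute_cov_shared_middle(y0, y1, y2):
    n1 = len(y1)
    return sum(
        (np.mean([x < yj for x in y0]) - 0.5) * (np.mean([yj < z for z in y2]) - 0.5)
        for yj in y1
    ) / n1**2


# --- grouping ---------------------------------------------------------------


class TestGrouping:
    def test_one_per_group(self):
        g = group_by_genotype([5, 6, 7], [0, 1, 2])
        assert g.counts == (1, 1, 1)

    def test_empty_third_group(self):
        g = group_by_genotype([1, 2, 3, 4], [0, 0, 1, 1])
        assert list(g.values0) == [1, 2]
        assert list(g.values1) == [3, 4]
        assert g.n2 == 0

    def test_permutation_invariance(self, rng):
        y = rng.normal(size=30)
        g = rng.integers(0, 3, size=30)
        perm = rng.permutation(30)
        a = z1_statistic(group_by_genotype(y, g))
        b = z1_statistic(group_by_genotype(y[perm], g[perm]))
        assert a.statistic == b.statistic

    def test_length_mismatch(self):
        with pytest.raises(InputError, match="equal length"):
            group_by_genotype([1, 2], [0, 1, 2])

    def test_bad_genotype_names_index(self):
        with pytest.raises(InputError, match="index 2"):
            group_by_genotype([1, 2, 3], [0, 1, 3])


# --- win probabilities ------------------------------------------------------


class TestWinProb:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2], [3, 4], 1.0),      # complete separation
            ([3, 4], [1, 2], 0.0),
            ([1, 4], [2, 3, 5], 4 / 6),
        ],
    )
    def test_examples(self, a, b, expected):
        assert win_prob(a, b) == pytest.approx(expected)

    def test_empty_group_raises(self):
        with pytest.raises(InputError, match="empty genotype group"):
            win_prob([], [1.0])

    @given(
        a=st.lists(st.integers(-20, 20), min_size=1, max_size=8),
        b=st.lists(st.integers(-20, 20), min_size=1, max_size=8),
        ties=st.sampled_from(["strict", "midrank"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, a, b, ties):
        assert win_prob(a, b, ties) == pytest.approx(brute_win_prob(a, b, ties))

    @given(
        a=st.lists(st.integers(-50, 50), min_size=1, max_size=10, unique=True),
        b=st.lists(st.integers(-50, 50), min_size=1, max_size=10, unique=True),
    )
    @settings(max_examples=100, deadline=None)
    def test_no_ties_complement(self, a, b):
        # evens vs odds: all values distinct across the two groups
        a = [2 * x for x in a]
        b = [2 * x + 1 for x in b]
        assert win_prob(a, b) + win_prob(b, a) == pytest.approx(1.0)

    def test_midrank_scores_ties_half(self):
        assert win_prob([1.0, 1.0], [1.0, 1.0], ties="midrank") == pytest.approx(0.5)


class TestVarianceCov:
    def test_frozen_example(self):
        assert win_prob_variance([1, 2], [3, 4]) == pytest.approx(0.1875)

    @given(
        a=st.lists(st.integers(-20, 20), min_size=2, max_size=8),
        b=st.lists(st.integers(-20, 20), min_size=2, max_size=8),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_and_lower_bound(self, a, b):
        v = win_prob_variance(a, b)
        assert v == pytest.approx(brute_variance(a, b))
        assert v >= 1 / (4 * len(a) * len(b)) - 1e-12

    def test_small_group_raises(self):
        with pytest.raises(InputError, match="size < 2"):
            win_prob_variance([1], [2, 3])

    def test_cov_shared_middle_frozen(self):
        # both centered comparison fractions equal 1/2 for each middle value
        got = win_prob_cov([1, 2], [3, 4], [5, 6], "shared-middle-01-12")
        assert got == pytest.approx(0.125)
        assert got == pytest.approx(brute_cov_shared_middle([1, 2], [3, 4], [5, 6]))

    @given(
        y0=st.lists(st.integers(-20, 20), min_size=2, max_size=6),
        y1=st.lists(st.integers(-20, 20), min_size=2, max_size=6),
        y2=st.lists(st.integers(-20, 20), min_size=2, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_cov_matches_brute_force(self, y0, y1, y2):
        got = win_prob_cov(y0, y1, y2, "shared-middle-01-12")
        assert got == pytest.approx(brute_cov_shared_middle(y0, y1, y2))

    def test_cov_symmetry_under_reversal(self, rng):
        # negating all values swaps comparison directions; the
        # shared-middle covariance is invariant because both centered
        # fractions flip sign
        y0, y1, y2 = rng.normal(size=5), rng.normal(size=6), rng.normal(size=7)
        a = win_prob_cov(y0, y1, y2, "shared-middle-01-12")
        b = win_prob_cov(-y2, -y1, -y0, "shared-middle-01-12")
        assert a == pytest.approx(b)

    def test_unknown_topology(self):
        with pytest.raises(InputError, match="topology"):
            win_prob_cov([1], [2], [3], "nope")

    def test_plugins_consistent_with_monte_carlo(self, rng):
        # the plug-in variance should track the sampling variance of the
        # win probability itself
        reps = 400
        vals, plugs = [], []
        for _ in range(reps):
            a, b = rng.normal(size=40), rng.normal(size=50)
            vals.append(win_prob(a, b))
            plugs.append(win_prob_variance(a, b))
        assert np.mean(plugs) == pytest.approx(np.var(vals, ddof=1), rel=0.2)


# --- statistics -------------------------------------------------------------


class TestZ1:
    def test_zero_when_f01_equals_f12(self):
        g = group_by_genotype([1, 4, 2, 5, 3, 6], [0, 0, 1, 1, 2, 2])
        assert z1_statistic(g).statistic == 0.0

    def test_dominant_leaning_sign(self):
        g = group_by_genotype([1, 2, 5, 6, 3, 4], [0, 0, 1, 1, 2, 2])
        assert z1_statistic(g).statistic > 0

    def test_requires_two_per_group(self):
        g = group_by_genotype([1, 2, 3, 4, 5], [0, 0, 1, 1, 2])
        with pytest.raises(DegenerateStatisticError):
            z1_statistic(g)

    def test_degenerate_variance_guard(self):
        # a crafted plug-in set whose Z1 denominator cancels exactly
        from twophase_npt.rank_stats import WinProbEstimates, _z1_from_estimates

        est = WinProbEstimates(
            f01=0.6, f12=0.4, f02=0.5,
            var01=0.1, var12=0.1, var02=0.1,
            cov01_12=0.1, cov02_12=0.0, cov01_02=0.0,
        )
        with pytest.raises(DegenerateStatisticError, match="degenerate variance"):
            _z1_from_estimates(est)


class TestNPT:
    def test_complete_separation(self, small_grouped):
        for model in ("REC", "ADD", "DOM"):
            res = npt_statistic(small_grouped, model)
            assert res.statistic > 0
            assert res.p_value < 0.5

    def test_additive_weights_sum_to_one(self, null_grouped):
        from twophase_npt.rank_stats import _additive_weights

        est = win_prob_estimates(null_grouped)
        w1, w2 = _additive_weights(null_grouped, est)
        assert w1 + w2 == pytest.approx(1.0)
        assert 0 < w1 < 1

    def test_p_value_recomputable_from_statistic(self, null_grouped):
        from scipy import stats

        for model in ("REC", "ADD", "DOM"):
            res = npt_statistic(null_grouped, model)
            assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(res.statistic)))

    def test_null_mean_and_variance(self, rng):
        from conftest import simulate_null_grouped

        zs = np.array(
            [
                [npt_statistic(simulate_null_grouped(300, 0.3, rng), m).statistic
                 for m in ("REC", "ADD", "DOM")]
                for _ in range(300)
            ]
        )
        assert np.abs(zs.mean(axis=0)).max() < 0.15
        assert np.abs(zs.var(axis=0) - 1).max() < 0.25


class TestKruskalWallis:
    def test_frozen_example(self, small_grouped):
        res = kruskal_wallis(small_grouped)
        assert res.statistic == pytest.approx(32 / 7)
        assert res.reference == "chi-squared(df=2)"

    def test_two_group_df(self):
        g = group_by_genotype([1, 2, 3, 4], [0, 0, 1, 1])
        assert kruskal_wallis(g).reference == "chi-squared(df=1)"

    def test_all_tied_raises(self):
        g = group_by_genotype([2.0] * 6, [0, 0, 1, 1, 2, 2])
        with pytest.raises(InputError, match="all observations tied"):
            kruskal_wallis(g)

    def test_null_size(self, rng):
        from scipy import stats as ss

        reps, hits = 2000, 0
        for _ in range(reps):
            y = rng.normal(size=90)
            g = rng.integers(0, 3, size=90)
            if kruskal_wallis(group_by_genotype(y, g)).p_value < 0.05:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 3 * se


class TestMax3:
    def test_statistic_is_max_abs(self, null_grouped):
        res = max3(null_grouped)
        zs = [abs(npt_statistic(null_grouped, m).statistic) for m in ("REC", "ADD", "DOM")]
        assert res.statistic == pytest.approx(max(zs))

    def test_permutation_deterministic(self, rng):
        y = rng.normal(size=60)
        g = rng.integers(0, 3, size=60)
        gt = group_by_genotype(y, g)
        a = max3(gt, "permutation", draws=200, seed=5)
        b = max3(gt, "permutation", draws=200, seed=5)
        assert a.p_value == b.p_value


class TestRankInvariance:
    """Every statistic depends only on within-pair orderings."""

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda x: x**3, lambda x: np.arctan(x) * 7 - 2]
    )
    def test_strictly_increasing_transform(self, rng, transform):
        y = rng.normal(size=120)
        g = rng.integers(0, 3, size=120)
        gt = group_by_genotype(y, g)
        gt2 = group_by_genotype(transform(y), g)
        assert z1_statistic(gt).statistic == z1_statistic(gt2).statistic
        for m in ("REC", "ADD", "DOM"):
            assert (
                npt_statistic(gt, m).statistic == npt_statistic(gt2, m).statistic
            )
        assert kruskal_wallis(gt).statistic == pytest.approx(
            kruskal_wallis(gt2).statistic
        )
        assert max3(gt).p_value == max3(gt2).p_value
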