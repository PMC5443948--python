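"""Chance nulls, Fisher/Welch statistics, groupwise and pairwise analyses."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from eggspace.partition import (
    binomial_wald_ci,
    compare_groups,
    expected_accuracy,
    fisher_exact_2x2,
    groupwise_analysis,
    pairwise_analysis,
    ranked_welch,
    summarize_counts,
)
from eggspace.simulate import (
    CommunitySpec,
    generate_community,
    make_species_specs,
)
from conftest import community_with_separation


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit enumeration with binomial coefficients."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = comb(n, col1)

    def prob(x):
        return comb(row1, x) * comb(n - row1, col1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def test_equal_two_group_sizes_give_half():
    prop, correct = expected_accuracy([50, 50])
    assert prop == 0.5 and correct == 50.0


def test_single_group_is_certain():
    prop, _ = expected_accuracy([37])
    assert prop == 1.0


def test_unequal_sizes_match_direct_sum_of_squares():
    prop, correct = expected_accuracy([80, 50, 30, 25, 20])
    assert prop == pytest.approx(10825 / 42025)
    assert correct == pytest.approx(10825 / 205)


@pytest.mark.parametrize("k", [2, 3, 7])
def test_equal_sizes_give_one_over_k(k):
    prop, _ = expected_accuracy([12] * k)
    assert prop == pytest.approx(1 / k)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.integers(1, 200), min_size=2, max_size=8))
def test_equal_split_minimizes_expected_accuracy(sizes):
    # Cauchy-Schwarz: sum n_i^2 >= N^2/k with equality at equal sizes
    prop, _ = expected_accuracy(sizes)
    assert prop >= 1 / len(sizes) - 1e-12


@pytest.mark.parametrize("correct, n, expected", [
    (169, 205, 5.21),
    (120, 219, 6.59),
    (216, 339, 5.12),
    (46, 46, 0.00),
    (0, 33, 0.00),
])
def test_wald_ci_reproduces_reference_halfwidths(correct, n, expected):
    assert binomial_wald_ci(correct, n) == pytest.approx(expected, abs=0.005)


def test_identical_rows_fisher_p_one():
    assert fisher_exact_2x2(10, 5, 10, 5) == pytest.approx(1.0)


def test_chance_vs_observed_counts_strongly_significant():
    # expected vs observed correct splits for a strongly partitioned group
    assert fisher_exact_2x2(44, 161, 169, 36) < 0.001


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
def test_fisher_matches_enumeration_oracle(a, b, c, d):
    assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
        fisher_enumeration_oracle(a, b, c, d), abs=1e-12)


@pytest.mark.parametrize("table", [(1, 9, 11, 3), (3, 3, 9, 1), (5, 0, 2, 7)])
def test_fisher_agrees_with_scipy(table):
    mine = fisher_exact_2x2(*table)
    ref = stats.fisher_exact([[table[0], table[1]], [table[2], table[3]]]).pvalue
    assert mine == pytest.approx(ref, rel=1e-9)


def test_all_zero_margin_returns_one():
    assert fisher_exact_2x2(0, 0, 0, 0) == 1.0


def test_identical_samples_welch_null():
    res = ranked_welch([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_complete_separation_significant_at_n5():
    res = ranked_welch([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
    assert res.statistic > 0
    assert res.p_value < 0.05


def test_ranked_welch_matches_hand_formula_on_fixture():
    a = [95.0, 92.0, 99.0, 90.0, 97.0, 94.0]
    b = [85.0, 88.0, 91.0, 80.0, 89.0, 86.0]
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra, rb = ranks[:6], ranks[6:]
    va, vb = ra.var(ddof=1), rb.var(ddof=1)
    t_hand = (ra.mean() - rb.mean()) / np.sqrt(va / 6 + vb / 6)
    df_hand = (va / 6 + vb / 6) ** 2 / ((va / 6) ** 2 / 5 + (vb / 6) ** 2 / 5)
    p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
    res = ranked_welch(a, b)
    assert res.statistic == pytest.approx(t_hand)
    assert res.df == pytest.approx(df_hand)
    assert res.p_value == pytest.approx(p_hand)
    # and against the reference Welch implementation applied to the ranks
    ref = stats.ttest_ind(ra, rb, equal_var=False)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)


def test_zero_separation_group_shows_no_improvement():
    table = community_with_separation([40, 40, 40], separation=0.0, seed=3)
    res = groupwise_analysis(table, "parasitized")
    assert abs(res.improvement_pct) < 12.0  # binomial noise around zero


def test_observed_equal_expected_gives_null_result():
    res = summarize_counts("parasitized", "dfa", {"a": 50, "b": 50}, 50)
    assert res.improvement_pct == 0.0
    assert res.fisher_p == pytest.approx(1.0)


def test_table_arithmetic_identities():
    res = summarize_counts("parasitized", "dfa",
                           dict(zip("abcde", [60, 45, 40, 32, 28])), 169)
    assert res.accuracy_pct == pytest.approx(100 * 169 / 205)
    assert res.improvement_pct == pytest.approx(
        res.accuracy_pct - 100 * res.expected_correct / res.n)


def test_high_separation_group_beats_low_separation_group():
    rng_hi = community_with_separation([40, 40, 40], separation=1.2, seed=4)
    lo = community_with_separation([40, 40, 40], separation=0.2, seed=5,
                                   parasitized=False)
    hi_res = groupwise_analysis(rng_hi, "parasitized")
    lo_res = groupwise_analysis(lo, "unparasitized")
    assert hi_res.accuracy_pct > lo_res.accuracy_pct
    assert compare_groups(hi_res, lo_res) < 0.05


def test_five_species_give_ten_pairs():
    table = community_with_separation([15, 15, 15, 15, 15], separation=0.5, seed=6)
    res = pairwise_analysis(table, "parasitized")
    assert len(res.pairs) == 10


def test_equal_size_pair_expected_is_half():
    table = community_with_separation([20, 20], separation=0.5, seed=7)
    res = pairwise_analysis(table, "parasitized")
    assert res.pairs.loc[0, "expected_pct"] == pytest.approx(50.0)


def test_identical_distribution_pair_observed_near_expected():
    table = community_with_separation([60, 60], separation=0.0, seed=8)
    res = pairwise_analysis(table, "parasitized")
    # binomial tolerance: ~3 SE at n=120 around the 50% expectation
    assert abs(res.pairs.loc[0, "observed_pct"] - 50.0) < 15.0


def test_groupwise_logistic_method_runs(small_community):
    res = groupwise_analysis(small_community, "parasitized", method="logistic")
    assert 0 <= res.accuracy_pct <= 100
    assert res.observed_correct <= res.n
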