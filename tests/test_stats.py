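"""Exact nonparametric statistics: brute-force equivalence, closed-form
small-sample values, and invariance properties."""

from itertools import combinations, product

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from b63osc import (kruskal, mean_ci95, one_sample_signed_rank,
                    paired_signed_rank, rank_sum_exact, signed_rank_exact)
from b63osc import TestResult as ExactTestResult  # alias avoids pytest collection


def brute_signed_rank_p(diffs):
    """Two-tailed exact signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(diffs, float)
    d = d[d != 0.0]
    ranks = sps.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    sums = [np.sum(ranks[np.array(signs, bool)]) if any(signs) else 0.0
            for signs in product([0, 1], repeat=d.size)]
    sums = np.asarray(sums)
    total = sums.size
    lo = np.sum(sums <= obs + 1e-9) / total
    hi = np.sum(sums >= obs - 1e-9) / total
    return min(1.0, 2.0 * min(lo, hi))


def brute_rank_sum_p(x, y):
    """Two-tailed exact Mann-Whitney p by enumerating group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1 = x.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = []
    for subset in combinations(range(combined.size), n1):
        us.append(ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0)
    us = np.asarray(us)
    lo = np.mean(us <= obs + 1e-9)
    hi = np.mean(us >= obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi))


# ---------------------------------------------------------------------------
# brute-force equivalence


def test_signed_rank_matches_brute_force_up_to_n12():
    rng = np.random.default_rng(7)
    for n in range(1, 13):
        for _ in range(3):
            d = np.round(rng.normal(0, 2, n), 2)
            d = d[d != 0.0]
            if d.size == 0:
                continue
            res = signed_rank_exact(d)
            assert res.p_value == pytest.approx(brute_signed_rank_p(d), abs=1e-12)


def test_signed_rank_with_tied_magnitudes_matches_brute_force():
    cases = [[1.0, -1.0, 2.0, 2.0, 3.0],
             [0.5, 0.5, 0.5, -0.5],
             [1.0, 1.0, -2.0, 2.0, -3.0, 3.0]]
    for d in cases:
        res = signed_rank_exact(d)
        assert res.has_ties
        assert res.p_value == pytest.approx(brute_signed_rank_p(d), abs=1e-12)


def test_rank_sum_matches_brute_force_small_groups():
    rng = np.random.default_rng(11)
    for n1, n2 in [(2, 3), (3, 3), (4, 4), (5, 5), (6, 6), (3, 7)]:
        x = np.round(rng.normal(0, 5, n1), 3)
        y = np.round(rng.normal(1, 5, n2), 3)
        res = rank_sum_exact(x, y)
        assert res.p_value == pytest.approx(brute_rank_sum_p(x, y), abs=1e-12)


def test_rank_sum_with_ties_matches_brute_force():
    x = [1.0, 2.0, 2.0, 5.0]
    y = [2.0, 3.0, 4.0, 4.0]
    res = rank_sum_exact(x, y)
    assert res.has_ties
    assert res.p_value == pytest.approx(brute_rank_sum_p(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# closed-form anchors


def test_all_same_sign_minimal_p_values():
    # With every difference positive the statistic is its maximum; the exact
    # two-tailed p is 2 / 2^n.
    for n, expect in [(6, 2.0 / 64), (9, 2.0 / 512), (12, 2.0 / 4096)]:
        res = signed_rank_exact(np.arange(1.0, n + 1.0))
        assert res.p_value == pytest.approx(expect, abs=1e-15)
        assert res.statistic == pytest.approx(n * (n + 1) / 2.0)


def test_seven_of_eight_one_small_discordant():
    res = one_sample_signed_rank([-0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    assert res.statistic == pytest.approx(35.0)
    assert res.p_value == pytest.approx(4.0 / 256.0, abs=1e-15)


def test_mann_whitney_u3_six_vs_six():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 35.0]
    y = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
    res = rank_sum_exact(x, y)
    assert res.statistic == pytest.approx(3.0)
    assert res.p_value == pytest.approx(14.0 / 924.0, abs=1e-15)


def test_scipy_cross_check_tie_free():
    rng = np.random.default_rng(3)
    d = rng.normal(0.5, 1, 10)
    res = signed_rank_exact(d)
    ref = sps.wilcoxon(d, mode="exact")
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
    x, y = rng.normal(0, 1, 7), rng.normal(1, 1, 8)
    res2 = rank_sum_exact(x, y)
    ref2 = sps.mannwhitneyu(x, y, method="exact")
    assert res2.p_value == pytest.approx(ref2.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# properties and edge cases


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(min_value=-50, max_value=50).filter(lambda v: abs(v) > 1e-6),
                min_size=1, max_size=12),
       st.floats(min_value=0.1, max_value=10.0))
def test_signed_rank_scale_invariant(diffs, scale):
    base = signed_rank_exact(diffs)
    scaled = signed_rank_exact(np.asarray(diffs) * scale)
    assert scaled.p_value == pytest.approx(base.p_value, abs=1e-12)
    assert scaled.statistic == pytest.approx(base.statistic)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=8,
                unique=True),
       st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=8,
                unique=True))
def test_rank_sum_symmetric_in_groups(x, y):
    res_xy = rank_sum_exact(x, y)
    res_yx = rank_sum_exact(y, x)
    assert res_xy.p_value == pytest.approx(res_yx.p_value, abs=1e-12)
    # U_x + U_y = n1 * n2
    assert res_xy.statistic + res_yx.statistic == pytest.approx(len(x) * len(y))


def test_degenerate_all_zero_differences_returns_none():
    assert signed_rank_exact([0.0, 0.0, 0.0]) is None
    assert paired_signed_rank([1.0, 2.0], [1.0, 2.0]) is None


def test_zeros_dropped_counted():
    res = signed_rank_exact([0.0, 1.0, -2.0, 0.0, 3.0])
    assert res.zeros_dropped == 2
    assert res.n == 3


def test_paired_equals_one_sample_on_differences():
    x = np.array([3.0, 5.0, 2.0, 8.0])
    y = np.array([1.0, 6.0, 0.5, 2.0])
    assert paired_signed_rank(x, y).p_value == pytest.approx(
        one_sample_signed_rank(x - y).p_value)


def test_input_validation():
    with pytest.raises(ValueError):
        signed_rank_exact([])
    with pytest.raises(ValueError):
        signed_rank_exact([1.0, np.nan])
    with pytest.raises(ValueError):
        rank_sum_exact([], [1.0])
    with pytest.raises(ValueError):
        paired_signed_rank([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        ExactTestResult("V", 1.0, 0.0, n=3)


def test_mean_ci95_matches_t_interval():
    v = np.array([58.0, 61.0, 55.0, 63.0, 57.0])
    mean, half = mean_ci95(v)
    lo, hi = sps.t.interval(0.95, v.size - 1, loc=v.mean(),
                            scale=sps.sem(v))
    assert mean == pytest.approx(v.mean())
    assert mean - half == pytest.approx(lo)
    assert mean + half == pytest.approx(hi)


def test_kruskal_matches_scipy():
    g1, g2, g3 = [1.0, 2, 3], [2.0, 4, 6], [5.0, 7, 9]
    res = kruskal(g1, g2, g3)
    ref = sps.kruskal(g1, g2, g3)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)
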