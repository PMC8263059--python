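"""Exact small-sample nonparametric tests and t-based confidence intervals.

Sample sizes in paired electrophysiology experiments are typically 4-15
preparations, far below the regime where normal approximations to rank
statistics are trustworthy.  Everything here is therefore *exact*: two-tailed
p-values are computed from the full combinatorial null distribution of the
statistic rather than from an asymptotic formula.

Conventions (they matter at these sample sizes):

* Wilcoxon signed-rank: zero differences are dropped before ranking
  (Wilcoxon's original treatment); tied absolute differences receive
  mid-ranks.  The statistic ``V`` is the sum of the ranks of positive
  differences, and the two-tailed p doubles the smaller tail of the exact
  sign-flip distribution, capped at 1.  The distribution is obtained by a
  shift convolution over the (doubled, hence integer) ranks, which counts all
  2^n sign assignments exactly.
* Mann-Whitney: ``W`` is the U statistic of the first sample (number of
  (x, y) pairs with x > y, ties counting one half).  Tie-free inputs use the
  classical partition recursion over all C(n1+n2, n1) group assignments;
  tied inputs fall back to explicit enumeration (feasible for n1+n2 <= 16).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    """Outcome of an exact nonparametric test.

    ``statistic_name`` is 'V0' (one-sample signed rank), 'V' (paired signed
    rank), 'W' (Mann-Whitney U of the first sample) or 'H' (Kruskal-Wallis,
    convenience only).  ``n2`` is None for one-sample tests.
    """

    statistic_name: str
    statistic: float
    p_value: float
    n: int
    n2: Optional[int] = None
    has_ties: bool = False
    zeros_dropped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _signed_rank_null_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled rank-sum over all sign assignments.

    ``counts[s]`` = number of the 2^n sign vectors whose positive-rank sum
    equals s/2.  Doubling makes mid-ranks integral; counts stay below 2^53
    for any n this package accepts, so float64 arithmetic is exact.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def _two_tailed_from_counts(counts: np.ndarray, observed_doubled: int) -> float:
    total = counts.sum()
    lo = counts[: observed_doubled + 1].sum() / total
    hi = counts[observed_doubled:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def signed_rank_exact(differences: Sequence[float],
                      statistic_name: str = "V") -> Optional[TestResult]:
    """Exact two-tailed Wilcoxon signed-rank test on paired differences.

    Returns None when every difference is zero (the test is degenerate and
    carries no information, an absence indicator rather than p = 1).
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("differences must be a non-empty 1-d sequence")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences contain non-finite values")
    nz = d[d != 0.0]
    zeros = d.size - nz.size
    if nz.size == 0:
        return None
    if nz.size > 64:
        raise ValueError("exact signed-rank test limited to n <= 64 non-zero differences")
    ranks = sps.rankdata(np.abs(nz))
    has_ties = np.unique(np.abs(nz)).size < nz.size
    v = float(ranks[nz > 0].sum())
    doubled = np.rint(2.0 * ranks).astype(int)
    counts = _signed_rank_null_counts(doubled)
    p = _two_tailed_from_counts(counts, int(round(2.0 * v)))
    return TestResult(statistic_name, v, p, n=int(nz.size),
                      has_ties=has_ties, zeros_dropped=zeros)


def one_sample_signed_rank(values: Sequence[float], mu: float = 0.0) -> Optional[TestResult]:
    """One-sample Wilcoxon signed-rank test against a theoretical value (V0)."""
    return signed_rank_exact(np.asarray(values, float) - mu, statistic_name="V0")


def paired_signed_rank(x: Sequence[float], y: Sequence[float]) -> Optional[TestResult]:
    """Within-group paired comparison (V statistic) of two matched datasets."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return signed_rank_exact(x - y, statistic_name="V")


def _bounded_partition_counts(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of partitions of u into at most n1 parts, each <= n2.

    This is the exact tie-free null distribution of the Mann-Whitney U
    statistic: counts sum to C(n1+n2, n1) and counts[u] is the number of
    group-label arrangements with U = u.  Computed as the Gaussian binomial
    coefficient [n1+n2 choose n1]_q, numerically exact in float64 for the
    sample sizes this package accepts.
    """
    max_u = n1 * n2
    # Gaussian binomial [n1+n2 choose n1]_q coefficients via iterated
    # polynomial multiplication: prod_{i=1..n1} (1 - q^(n2+i)) / (1 - q^i).
    coeffs = np.zeros(max_u + 1)
    coeffs[0] = 1.0
    for i in range(1, n1 + 1):
        # multiply by (1 - q^(n2+i)), then divide by (1 - q^i)
        nxt = coeffs.copy()
        if n2 + i <= max_u:
            nxt[n2 + i:] -= coeffs[: max_u + 1 - (n2 + i)]
        # synthetic division by (1 - q^i): running sum with stride i
        for u in range(i, max_u + 1):
            nxt[u] += nxt[u - i]
        coeffs = nxt
    return coeffs


def rank_sum_exact(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Exact two-tailed Mann-Whitney test; W is the U statistic of ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("group data contain non-finite values")
    n1, n2 = int(x.size), int(y.size)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = float(r1 - n1 * (n1 + 1) / 2.0)
    has_ties = np.unique(combined).size < combined.size
    if not has_ties:
        counts = _bounded_partition_counts(n1, n2)
        p = _two_tailed_from_counts(counts, int(round(u1)))
    else:
        if n1 + n2 > 16:
            raise ValueError("exact Mann-Whitney with ties limited to n1 + n2 <= 16")
        # enumerate which rank positions belong to group 1; U depends only on
        # the multiset of ranks, so enumerate index subsets explicitly.
        doubled = np.rint(2.0 * ranks).astype(int)
        obs = int(round(2.0 * u1))
        base = n1 * (n1 + 1)  # doubled version of n1(n1+1)/2
        lo = hi = total = 0
        for subset in combinations(range(n1 + n2), n1):
            u2 = int(sum(doubled[list(subset)])) - base
            total += 1
            if u2 <= obs:
                lo += 1
            if u2 >= obs:
                hi += 1
        p = min(1.0, 2.0 * min(lo / total, hi / total))
    return TestResult("W", u1, p, n=n1, n2=n2, has_ties=has_ties)


def mean_ci95(values: Sequence[float]) -> tuple[float, float]:
    """Mean and t-based 95% confidence half-width, ``t(0.975, n-1) * sd / sqrt(n)``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for a confidence interval")
    n = v.size
    half = float(sps.t.ppf(0.975, n - 1) * v.std(ddof=1) / np.sqrt(n))
    return float(v.mean()), half


def kruskal(*groups: Sequence[float]) -> TestResult:
    """Kruskal-Wallis H across >= 2 groups (chi-square approximation).

    Convenience wrapper only; the exact machinery above is the package's
    acceptance surface for two-sample comparisons.
    """
    h, p = sps.kruskal(*groups)
    return TestResult("H", float(h), float(p), n=sum(len(g) for g in groups))
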