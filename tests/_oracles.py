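"""Independent brute-force oracles used to check closed-form / vectorized code.

Everything here is deliberately naive: exact integer arithmetic and explicit
enumeration, with no shared code paths with the package under test.
"""

from __future__ import annotations

import itertools
import math
from bisect import bisect_right
from fractions import Fraction

import numpy as np

_SLACK_NUM = 10**7 + 1  # mirrors the (1 + 1e-7) probability-mass tie slack
_SLACK_DEN = 10**7


def fisher_two_sided_oracle(m1: int, t1: int, m2: int, t2: int) -> float:
    """Two-sided exact test by full enumeration with integer arithmetic."""
    m = m1 + m2
    lo, hi = max(0, m - t2), min(t1, m)
    nums = [math.comb(t1, k) * math.comb(t2, m - k) for k in range(lo, hi + 1)]
    denom = math.comb(t1 + t2, m)
    obs = nums[m1 - lo]
    total = sum(n for n in nums if n * _SLACK_DEN <= obs * _SLACK_NUM)
    return min(total / denom, 1.0)


def fisher_oracle_family(t1: int, t2: int, m: int):
    """Yield (m1, p) for every observable table of the margin family (t1, t2, m).

    Sorted-prefix enumeration: p for an observed numerator is the prefix sum
    of all numerators at or below it (with the tie slack).
    """
    lo, hi = max(0, m - t2), min(t1, m)
    nums = [math.comb(t1, k) * math.comb(t2, m - k) for k in range(lo, hi + 1)]
    denom = math.comb(t1 + t2, m)
    snums = sorted(nums)
    prefix = list(itertools.accumulate(snums))
    for i, n in enumerate(nums):
        j = bisect_right(snums, n * _SLACK_NUM // _SLACK_DEN)
        yield lo + i, min(prefix[j - 1] / denom, 1.0)


def hypergeom_upper_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by summing exact hypergeometric masses."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return float(total)


def hypergeom_subset_enumeration(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by literally enumerating every size-n draw from N items."""
    hits = 0
    total = 0
    marked = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def binomial_upper_tail_oracle(m: int, n: int, p: float) -> float:
    """P(X >= m) for X ~ Binomial(n, p) by explicit summation."""
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(m, n + 1))


def tom_bruteforce(adj: np.ndarray) -> np.ndarray:
    """Topological overlap by literal triple loops."""
    a = adj.astype(float).copy()
    n = a.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (shared + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return out


def quadrant_truth_table(log2fc: float, meth_diff: float, fc_t: float = 1.0, md_t: float = 25.0) -> int:
    """Quadrant by an explicit nine-way case analysis."""
    up = log2fc > fc_t
    down = log2fc < -fc_t
    hypo = meth_diff < -md_t
    hyper = meth_diff > md_t
    if up and hypo:
        return 1
    if up and hyper:
        return 3
    if up:
        return 2
    if down and hypo:
        return 7
    if down and hyper:
        return 9
    if down:
        return 8
    if hypo:
        return 4
    if hyper:
        return 6
    return 5


def spearman_midrank_oracle(x, y) -> float:
    """Spearman rho via brute-force midranks and the Pearson formula."""

    def midranks(v):
        v = list(v)
        out = []
        for a in v:
            less = sum(1 for b in v if b < a)
            equal = sum(1 for b in v if b == a)
            out.append(less + (equal + 1) / 2.0)
        return np.array(out)

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
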