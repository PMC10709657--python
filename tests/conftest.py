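"""Shared fixtures and independent naive oracles.

The oracles here deliberately avoid the package's own code paths:
overlap counts come from Python set intersection, tail probabilities
from exact rational arithmetic (small n) or full-support log-PMF
summation, and minima from exhaustive enumeration.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from rankoverlap.ranked_io import QUADRANTS, RankedList


# ---------------------------------------------------------------- oracles


def rational_tails(c: int, i: int, j: int, n: int) -> tuple[float, float]:
    """Exact hypergeometric tails by rational enumeration; returns
    (ln P(X >= c), ln P(X <= c)) with c clamped to the support."""
    kmin = max(0, i + j - n)
    kmax = min(i, j)
    c = max(c, kmin)
    tot = math.comb(n, j)
    upper = sum(
        Fraction(math.comb(i, k) * math.comb(n - i, j - k), tot)
        for k in range(c, kmax + 1)
    )
    lower = sum(
        Fraction(math.comb(i, k) * math.comb(n - i, j - k), tot)
        for k in range(kmin, c + 1)
    )
    return math.log(upper), math.log(lower)


def logsumexp_tails(c: int, i: int, j: int, n: int) -> tuple[float, float]:
    """Floating oracle: full-support log-PMF summation via scipy."""
    from scipy.special import logsumexp
    from scipy.stats import hypergeom

    kmin = max(0, i + j - n)
    kmax = min(i, j)
    c = max(c, kmin)
    ks = np.arange(kmin, kmax + 1)
    lp = hypergeom.logpmf(ks, n, i, j)
    upper = logsumexp(lp[ks >= c])
    lower = logsumexp(lp[ks <= c])
    return float(upper), float(lower)


def naive_overlap(a_order, b_order, i: int, j: int) -> int:
    return len(set(map(str, a_order[:i])) & set(map(str, b_order[:j])))


def naive_two_sided(c: int, i: int, j: int, n: int) -> tuple[float, int]:
    up, lo = logsumexp_tails(c, i, j, n)
    sign = -1 if lo < up - 1e-12 else +1
    return min(0.0, math.log(2.0) + min(up, lo)), sign


def exhaustive_min(frame, expected_sign: int) -> tuple[float, tuple[int, int], int]:
    """Brute-force minimal two-sided log P over a quadrant, honouring the
    quadrant sign expectation; returns (log_p, (i, j), overlap)."""
    n = frame.n
    best = (math.inf, (0, 0), -1)
    order_a = np.argsort(frame.pos_a)
    order_b = np.argsort(frame.pos_b)
    pos_b_of = frame.pos_b
    inb = np.zeros(n, dtype=bool)
    for i in range(1, frame.max_i + 1):
        members_a = order_a[:i]
        ranks_in_b = np.sort(pos_b_of[members_a])
        for j in range(1, frame.max_j + 1):
            c = int(np.searchsorted(ranks_in_b, j))
            lp, sign = naive_two_sided(c, i, j, n)
            if frame.anticorrelated:
                sign = -sign
            if sign == expected_sign and lp < best[0] - 1e-12:
                best = (lp, (i, j), c)
    return best


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ranked_pair(n: int, seed: int) -> tuple[RankedList, RankedList]:
    g = np.random.default_rng(seed)
    labels = np.array([f"g{k:05d}" for k in range(n)], dtype=object)
    vals = (np.arange(n) - n // 2 + 0.5) / n
    return (
        RankedList(labels=labels, values=g.permutation(vals)),
        RankedList(labels=labels, values=g.permutation(vals)),
    )


@pytest.fixture
def small_pair():
    return random_ranked_pair(60, seed=7)
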