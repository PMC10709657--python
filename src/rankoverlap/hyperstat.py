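"""Underflow-safe signed hypergeometric enrichment statistics.

Every cell of an overlap map is a hypergeometric tail probability: with a
universe of ``n`` features, an overlap of ``c`` features between a prefix
of ``i`` features of one list and ``j`` of the other,

* enrichment is measured by the upper tail ``P(X >= c)``,
* depletion (anticorrelation) by the lower tail ``P(X <= c)``,
* the two-sided statistic is ``2 * min(upper(c), lower(c))`` capped at 1,
  negatively signed when the lower tail attains the minimum.

For transcript-scale lists these probabilities routinely underflow double
precision (values far below 1e-308), so everything here is computed and
returned on the natural-log scale: the log-PMF is evaluated through log
gamma functions and each tail is accumulated with the one-term PMF
recurrence in log space, always summing the *short* tail (the side on
which the PMF is decaying) and recovering the other tail by complement.
Values as small as ``exp(-10000)`` remain finite and accurate.

Natural logarithms are used throughout the package: the conventional map
display threshold 3 corresponds to ``-ln(0.05)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SignedLogP",
    "log_hyper_upper",
    "log_hyper_lower",
    "signed_log_pvalue",
    "log_tails_batch",
    "signed_log_pvalue_batch",
]

Mode = Literal["one_sided", "two_sided"]

# Stop accumulating a tail once the bound on the remaining mass is this
# many nats below the running sum (well past double-precision resolution).
_TAIL_CUTOFF = 45.0


@dataclass(frozen=True)
class SignedLogP:
    """A natural-log P-value with a direction sign.

    ``sign`` is +1 for enrichment (correlation) and -1 for depletion
    (anticorrelation, lower hypergeometric tail).  ``log_p`` is capped at
    0 (P = 1).
    """

    log_p: float
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if self.log_p > 0.0:
            raise ValueError(f"log_p must be <= 0, got {self.log_p}")

    @property
    def p(self) -> float:
        """The P-value on the natural scale (may underflow to 0.0)."""
        return float(np.exp(self.log_p))


def _validate(c, i, j, n) -> None:
    c, i, j, n = (np.asarray(x) for x in (c, i, j, n))
    if np.any((i < 1) | (i > n) | (j < 1) | (j > n)):
        raise ValueError("prefix lengths must satisfy 1 <= i, j <= n")
    if np.any((c < 0) | (c > np.minimum(i, j))):
        raise ValueError("overlap must satisfy 0 <= c <= min(i, j)")


def _log_pmf(k, i, j, n):
    """ln P(X = k) for X ~ Hypergeometric(population n, i successes, j draws)."""
    k = np.asarray(k, dtype=np.float64)
    i = np.asarray(i, dtype=np.float64)
    j = np.asarray(j, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    return (
        gammaln(j + 1)
        - gammaln(k + 1)
        - gammaln(j - k + 1)
        + gammaln(n - j + 1)
        - gammaln(i - k + 1)
        + gammaln(i + 1)
        + gammaln(n - i + 1)
        - gammaln(n - j - i + k + 1)
        - gammaln(n + 1)
    )


def _accumulate_tail(start, i, j, n, kmin, kmax, upward: bool) -> np.ndarray:
    """Log-sum of PMF terms from ``start`` to the support edge, elementwise.

    Only called on the decaying side of the mode, so terms shrink
    monotonically and the geometric remainder bound permits early exit.
    Entries whose ``start`` lies outside the support contribute -inf.
    """
    start = np.asarray(start, dtype=np.int64)
    shape = start.shape
    total = np.full(shape, -np.inf)
    inside = (start >= kmin) & (start <= kmax)
    if not np.any(inside):
        return total
    idx = np.flatnonzero(inside)
    k = start[idx].astype(np.float64)
    ii = np.broadcast_to(i, shape).astype(np.float64)[idx]
    jj = np.broadcast_to(j, shape).astype(np.float64)[idx]
    nn = np.broadcast_to(n, shape).astype(np.float64)[idx]
    klim = (np.broadcast_to(kmax, shape) if upward else np.broadcast_to(kmin, shape))
    klim = klim[idx].astype(np.float64)
    term = _log_pmf(k, ii, jj, nn)
    acc = term.copy()
    block = 24
    steps = np.arange(block, dtype=np.float64)
    if not upward:
        steps = -steps
    while idx.size:
        # Advance `block` recurrence terms at once: log-ratios evaluated at
        # k, k+1, ... accumulate by cumulative sum into the next log-terms.
        ks = k[:, None] + steps[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            if upward:
                lr = (
                    np.log((ii[:, None] - ks) * (jj[:, None] - ks))
                    - np.log(
                        (ks + 1.0) * (nn[:, None] - ii[:, None] - jj[:, None] + ks + 1.0)
                    )
                )
                lr = np.where(ks >= klim[:, None], -np.inf, lr)
            else:
                lr = (
                    np.log(ks * (nn[:, None] - ii[:, None] - jj[:, None] + ks))
                    - np.log((ii[:, None] - ks + 1.0) * (jj[:, None] - ks + 1.0))
                )
                lr = np.where(ks <= klim[:, None], -np.inf, lr)
            csum = np.cumsum(lr, axis=1)
            block_terms = term[:, None] + csum
            block_max = np.max(block_terms, axis=1)
            safe_max = np.where(np.isfinite(block_max), block_max, 0.0)
            block_sum = safe_max + np.log(
                np.sum(np.exp(block_terms - safe_max[:, None]), axis=1)
            )
            block_sum = np.where(np.isfinite(block_max), block_sum, -np.inf)
        acc = np.logaddexp(acc, block_sum)
        total[idx] = acc
        term = block_terms[:, -1]
        k = k + (block if upward else -block)
        last_lr = lr[:, -1]
        # Geometric bound on everything still to come.
        with np.errstate(divide="ignore", invalid="ignore"):
            rem = term - np.log1p(-np.exp(np.minimum(last_lr, -1e-12)))
        rem = np.where(np.isfinite(last_lr), rem, -np.inf)
        cont = rem > acc - _TAIL_CUTOFF
        if not np.any(cont):
            break
        keep = np.flatnonzero(cont)
        idx, k, ii, jj, nn, klim = (
            idx[keep], k[keep], ii[keep], jj[keep], nn[keep], klim[keep],
        )
        term, acc = term[keep], acc[keep]
    return total


def log_tails_batch(c, i, j, n) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise ``(ln P(X >= c), ln P(X <= c))`` in log space.

    Overlaps below the support minimum ``max(0, i + j - n)`` are clamped
    to it before evaluation.  ``P(X >= support_min)`` and
    ``P(X <= support_max)`` are exactly 0 in log space.
    """
    c, i, j, n = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(x, dtype=np.int64)) for x in (c, i, j, n))
    )
    _validate(c, i, j, n)
    kmin = np.maximum(0, i + j - n)
    kmax = np.minimum(i, j)
    c = np.maximum(c, kmin)
    mode = ((i + 1) * (j + 1)) // (n + 2)
    mode = np.clip(mode, kmin, kmax)

    log_upper = np.zeros(c.shape)
    log_lower = np.zeros(c.shape)

    log_pmf_c = _log_pmf(c, i, j, n)

    def _complement(excl_log: np.ndarray) -> np.ndarray:
        # 1 - excluded tail; the complement always contains the term at c,
        # which guards against rounding when the excluded tail is ~1.
        with np.errstate(divide="ignore"):
            comp = np.log1p(-np.exp(np.minimum(excl_log, -1e-17)))
        return np.maximum(comp, log_pmf_c)

    # Upper side of the mode: sum P(X >= c) directly, complement the rest.
    hi = c > mode
    if np.any(hi):
        excl = _accumulate_tail(c + 1, i, j, n, kmin, kmax, upward=True)
        up = np.logaddexp(log_pmf_c, excl)
        log_upper = np.where(hi, up, log_upper)
        log_lower = np.where(hi, _complement(excl), log_lower)
    # At or below the mode: sum P(X <= c) directly instead.
    lo_side = ~hi
    if np.any(lo_side):
        excl = _accumulate_tail(c - 1, i, j, n, kmin, kmax, upward=False)
        low = np.logaddexp(log_pmf_c, excl)
        log_lower = np.where(lo_side, low, log_lower)
        log_upper = np.where(lo_side, _complement(excl), log_upper)

    # Exact edges of the support.
    log_upper = np.where(c <= kmin, 0.0, np.minimum(log_upper, 0.0))
    log_lower = np.where(c >= kmax, 0.0, np.minimum(log_lower, 0.0))
    return log_upper, log_lower


def signed_log_pvalue_batch(c, i, j, n, mode: Mode = "two_sided"):
    """Elementwise signed log P-values.

    Returns ``(log_p, sign)`` arrays; ``sign`` is -1 where the lower tail
    attains the minimum of the two tails (depletion), +1 otherwise (ties
    resolve to enrichment).  For ``one_sided`` the log P is the upper
    (enrichment) tail; for ``two_sided`` it is ``ln 2 + min(tails)``
    capped at 0.
    """
    if mode not in ("one_sided", "two_sided"):
        raise ValueError(f"unknown mode {mode!r}")
    log_upper, log_lower = log_tails_batch(c, i, j, n)
    if mode == "one_sided":
        # The one-sided statistic is the enrichment tail itself; it never
        # "comes from the lower tail", so it is never negatively signed.
        return log_upper, np.ones_like(log_upper, dtype=np.int8)
    # Negative sign iff the lower tail strictly attains the minimum
    # (a small tolerance keeps ties at P ~ 1 resolving to enrichment).
    sign = np.where(log_lower < log_upper - 1e-12, -1, 1).astype(np.int8)
    log_p = np.minimum(np.log(2.0) + np.minimum(log_upper, log_lower), 0.0)
    return log_p, sign


def log_hyper_upper(c: int, i: int, j: int, n: int) -> float:
    """ln P(X >= c) for X ~ Hypergeometric(n, i, j)."""
    up, _ = log_tails_batch(c, i, j, n)
    return float(up[0])


def log_hyper_lower(c: int, i: int, j: int, n: int) -> float:
    """ln P(X <= c) for X ~ Hypergeometric(n, i, j)."""
    _, low = log_tails_batch(c, i, j, n)
    return float(low[0])


def signed_log_pvalue(
    c: int, i: int, j: int, n: int, mode: Mode = "two_sided"
) -> SignedLogP:
    """Signed log P-value of an overlap of ``c`` at coordinate ``(i, j)``."""
    log_p, sign = signed_log_pvalue_batch(c, i, j, n, mode)
    return SignedLogP(log_p=float(log_p[0]), sign=int(sign[0]))
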