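"""Synthetic ranked-list scenarios and the accuracy / type-I harnesses.

Five scenario families exercise the whole pipeline:

* ``identical`` — the two lists are the same: a perfect correlated
  diagonal; the dd and uu quadrants between them cover the whole list.
* ``reversed`` — the second list's statistics are negated: perfect
  anticorrelation, signal confined to du/ud with negative sign.
* ``four_block`` — four consecutive blocks alternating concordant /
  discordant, with the zero crossing at a configurable fraction of the
  lists (default two fifths): all four quadrants carry a diagonal signal.
* ``random`` — independent shuffles: no signal anywhere.
* ``planted`` — the accuracy benchmark: ``n_overlap`` labels placed
  uniformly at random within the top ``n_top`` down-regulated positions
  of both lists, everything else randomly ranked.  Defaults follow the
  benchmark convention of 19,962 features with 200 planted among the
  top 300.

Statistic values are ranks mapped to a symmetric interval around the
zero crossing — their magnitudes are irrelevant to rank statistics, only
the order and the split position matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .quadrants import RRHOConfig, run_rrho
from .ranked_io import RankedList

__all__ = [
    "PlantedScenario",
    "AccuracyReport",
    "make_scenario",
    "accuracy_metrics",
    "benchmark_accuracy",
    "type1_harness",
]

PLANTED_N = 19_962
PLANTED_OVERLAP = 200
PLANTED_TOP = 300
# Alternative preset: wide, diffuse planted blocks.
PLANTED_WIDE = dict(n_overlap_range=(1500, 2500), n_top_range=(3500, 4500))


@dataclass(frozen=True)
class PlantedScenario:
    """A planted-overlap instance with its ground truth."""

    list_a: RankedList
    list_b: RankedList
    planted: frozenset
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AccuracyReport:
    """Detection rates of a planted-overlap run."""

    tpr: float
    tnr: float
    accuracy: float
    n_detected: int


def _labels(n: int) -> np.ndarray:
    width = len(str(n))
    return np.array([f"g{k:0{width}d}" for k in range(n)], dtype=object)


def _values_for_split(n: int, split_fraction: float) -> np.ndarray:
    """Strictly increasing values with exactly round(split_fraction * n)
    strictly negative entries, mapped into [-1, 1]."""
    split = int(round(split_fraction * n))
    v = (np.arange(n, dtype=float) - split + 0.5) / n
    return v / max(abs(v[0]), abs(v[-1]))


def make_scenario(
    kind: str,
    n: int,
    seed: int = 0,
    split_fraction: Optional[float] = None,
    n_overlap: int = PLANTED_OVERLAP,
    n_top: int = PLANTED_TOP,
):
    """Generate one synthetic list pair.

    Returns ``(list_a, list_b)`` for the plain kinds and a
    :class:`PlantedScenario` for ``kind="planted"``.  The zero crossing
    defaults to the list midpoint, except for ``four_block`` where it
    sits at two fifths of the lists.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if split_fraction is None:
        split_fraction = 0.4 if kind == "four_block" else 0.5
    rng = np.random.default_rng(seed)
    labels = _labels(n)
    values = _values_for_split(n, split_fraction)

    if kind == "identical":
        a = RankedList(labels=labels, values=values)
        b = RankedList(labels=labels, values=values.copy())
        return a, b
    if kind == "reversed":
        a = RankedList(labels=labels, values=values)
        b = RankedList(labels=labels, values=-values)
        return a, b
    if kind == "four_block":
        return _four_block(n, labels, split_fraction)
    if kind == "random":
        a = RankedList(labels=labels, values=rng.permutation(values))
        b = RankedList(labels=labels, values=rng.permutation(values))
        return a, b
    if kind == "planted":
        if not (0 < n_overlap <= n_top <= n):
            raise ValueError("planted scenario needs n_overlap <= n_top <= n")
        planted = rng.choice(n, size=n_overlap, replace=False)
        vals = []
        for _ in range(2):
            # Planted labels land uniformly within the top n_top
            # down-regulated positions; everything else is randomly ranked.
            top_slots = rng.choice(n_top, size=n_overlap, replace=False)
            rest = np.setdiff1d(np.arange(n), planted)
            rest_slots = np.setdiff1d(np.arange(n), top_slots)
            pos = np.empty(n, dtype=np.int64)
            pos[planted] = top_slots
            pos[rest] = rng.permutation(rest_slots)
            vals.append(_values_for_split(n, split_fraction)[pos])
        a = RankedList(labels=labels, values=vals[0])
        b = RankedList(labels=labels, values=vals[1])
        return PlantedScenario(
            list_a=a,
            list_b=b,
            planted=frozenset(labels[planted].tolist()),
            params=dict(n=n, n_overlap=n_overlap, n_top=n_top, seed=seed),
        )
    raise ValueError(f"unknown scenario kind {kind!r}")


def _four_block(n: int, labels: np.ndarray, f: float) -> tuple[RankedList, RankedList]:
    """Half concordant, half discordant features, zero crossing at
    fraction ``f`` of both lists.

    Four direction-pure blocks: concordant-down (down in both lists),
    two discordant blocks of n/4 (down in one list, up in the other),
    and concordant-up.  Block ranks interleave evenly within each half
    of each list, so every quadrant carries a diagonal signal peaking
    mid-quadrant.  Requires 0.25 <= f <= 0.75.
    """
    if not 0.25 <= f <= 0.75:
        raise ValueError("four_block needs a split fraction in [0.25, 0.75]")
    d = n // 4  # each discordant block
    split = int(round(f * n))
    c1 = split - d  # concordant-down block
    c2 = n - split - d  # concordant-up block
    q1 = labels[:c1]
    q3 = labels[c1:c1 + d]  # down in a, up in b
    q4 = labels[c1 + d:c1 + 2 * d]  # up in a, down in b
    q2 = labels[c1 + 2 * d:]

    def interleave(block_x, keys_x, block_y, keys_y):
        lab = np.concatenate([block_x, block_y])
        keys = np.concatenate([keys_x, keys_y])
        return lab[np.argsort(keys, kind="stable")]

    def keys(size, reverse=False):
        k = (np.arange(size) + 0.5) / max(size, 1)
        return k[::-1] if reverse else k

    down_a = interleave(q1, keys(c1), q3, keys(d))
    up_a = interleave(q4, keys(d), q2, keys(c2))
    down_b = interleave(q1, keys(c1), q4, keys(d, reverse=True))
    up_b = interleave(q3, keys(d, reverse=True), q2, keys(c2))
    vals = _values_for_split(n, f)
    values_a = np.empty(n)
    values_b = np.empty(n)
    loc = pd.Index(labels)
    values_a[loc.get_indexer(np.concatenate([down_a, up_a]))] = vals
    values_b[loc.get_indexer(np.concatenate([down_b, up_b]))] = vals
    return (
        RankedList(labels=labels, values=values_a),
        RankedList(labels=labels, values=values_b),
    )


def accuracy_metrics(detected, planted, n: int) -> AccuracyReport:
    """TPR / TNR / accuracy of a detected label set vs the planted truth."""
    detected = set(map(str, detected))
    planted = set(map(str, planted))
    tp = len(detected & planted)
    fp = len(detected - planted)
    fn = len(planted) - tp
    tn = n - len(planted) - fp
    return AccuracyReport(
        tpr=tp / len(planted) if planted else 1.0,
        tnr=tn / (n - len(planted)) if n > len(planted) else 1.0,
        accuracy=(tp + tn) / n,
        n_detected=len(detected),
    )


def _bench_config(algorithm: str, step: Optional[int], seed: int,
                  generations: int, population: Optional[int]) -> RRHOConfig:
    return RRHOConfig(
        algorithm=algorithm,
        step=step,
        generations=generations,
        population=population,
        adjust="none",
        quadrant_names=("dd",),
        render_resolution=None,
        seed=seed,
    )


def benchmark_accuracy(
    replicates: int,
    algorithm: str = "ea",
    step: Optional[int] = None,
    n: int = PLANTED_N,
    n_overlap: int = PLANTED_OVERLAP,
    n_top: int = PLANTED_TOP,
    generations: int = 200,
    population: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy of the dd-quadrant detection over planted replicates.

    Each replicate generates an independent planted scenario, runs the
    requested search on the down-down quadrant, and scores the enriched
    set against the planted labels.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    root = np.random.SeedSequence((seed, 0xACC))
    for rep, ss in enumerate(root.spawn(replicates)):
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        sc = make_scenario("planted", n=n, seed=rep_seed,
                           n_overlap=n_overlap, n_top=n_top)
        cfg = _bench_config(algorithm, step, rep_seed, generations, population)
        res = run_rrho(sc.list_a, sc.list_b, cfg)
        dd = res.quadrants["dd"]
        rpt = accuracy_metrics(dd.enriched_labels, sc.planted, n)
        rows.append({
            "replicate": rep,
            "seed": rep_seed,
            "algorithm": algorithm,
            "step": step,
            "tpr": rpt.tpr,
            "tnr": rpt.tnr,
            "accuracy": rpt.accuracy,
            "n_detected": rpt.n_detected,
            "best_i": None if dd.best is None else dd.best.i,
            "best_j": None if dd.best is None else dd.best.j,
            "log_p": dd.log_p,
        })
    return pd.DataFrame(rows)


def type1_harness(
    n_pairs: int,
    n: int = 1000,
    permutations: int = 100,
    seed: int = 0,
    algorithm: str = "grid",
) -> dict:
    """Type-I error of the adjusted P-value on random list pairs.

    Runs the full pipeline (search + permutation adjustment, plain-
    permutation null) on independent random pairs and reports the
    fraction of pairs with any quadrant adjusted P < 0.05, together with
    the one-sided exact binomial tail of that count at the nominal rate
    0.05.
    """
    if n_pairs < 50:
        raise ValueError("need at least 50 pairs")
    root = np.random.SeedSequence((seed, 0x71))
    hits = 0
    per_pair = []
    for pair, ss in enumerate(root.spawn(n_pairs)):
        pair_seed = int(ss.generate_state(1)[0] % (2**31))
        a, b = make_scenario("random", n=n, seed=pair_seed)
        cfg = RRHOConfig(
            algorithm=algorithm,
            adjust="permute",
            permutations=permutations,
            render_resolution=None,
            seed=pair_seed,
        )
        res = run_rrho(a, b, cfg)
        min_adj = min(r.p_adjusted for r in res.quadrants.values())
        sig = any(r.p_adjusted < 0.05 for r in res.quadrants.values())
        hits += int(sig)
        per_pair.append(min_adj)
    frac = hits / n_pairs
    # One-sided exact test of conservativeness: probability of seeing at
    # most this many significant pairs if the true rate were 5%.
    binom_p = float(stats.binom.cdf(hits, n_pairs, 0.05))
    return {
        "n_pairs": n_pairs,
        "n": n,
        "permutations": permutations,
        "significant": hits,
        "fraction": frac,
        "binomial_tail_p": binom_p,
        "min_adjusted": per_pair,
    }
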