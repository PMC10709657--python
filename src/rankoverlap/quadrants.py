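"""Four-quadrant decomposition, per-quadrant search, and enrichment sets.

The zero crossing of each list splits the overlap map into four regions:
down-down (dd), up-up (uu), down-up (du) and up-down (ud).  Each quadrant
is searched in its own coordinate frame whose origin is the quadrant's
pair of list extremities; prefix lengths run up to the zero crossings.

The enriched label set of a quadrant is the intersection of the two
oriented prefixes at the best coordinate.  For the correlated quadrants
this is the familiar "top of both lists" set; for the anticorrelated
quadrants the same oriented intersection is, in global map terms, the
region between the best coordinate and the quadrant's outer corner —
the set the depletion signal points at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import hpp_adjust, hyperstat
from .minp_search import (
    BestCoordinate,
    EAParams,
    ea_search_frame,
    grid_search_frame,
)
from .overlap_engine import OverlapMap, QuadrantFrame, build_frame, render_map
from .ranked_io import QUADRANTS, QuadrantSpec, RankedList, align_lists

logger = logging.getLogger(__name__)

__all__ = [
    "RRHOConfig",
    "QuadrantResult",
    "RRHOResult",
    "quadrant_bounds",
    "enrichment_set",
    "run_rrho",
]

ALL_QUADRANTS = ("dd", "uu", "du", "ud")


@dataclass(frozen=True)
class RRHOConfig:
    """Configuration of a full overlap analysis."""

    algorithm: str = "ea"  # "ea" | "grid"
    step: Optional[int] = None  # grid stride; None -> floor(sqrt(n))
    generations: int = 200
    population: Optional[int] = None  # None -> 500 + floor(sqrt(n))
    elite_fraction: float = 0.2
    mutation_scale: Optional[float] = None
    mutation_prob: float = 0.5
    mode: hyperstat.Mode = "two_sided"
    adjust: str = "none"  # "none" | "permute" | "hpp"
    hpp_flavour: str = "fold_change"  # "fold_change" | "pvalue"
    permutations: int = 100
    quadrant_names: tuple[str, ...] = ALL_QUADRANTS
    render_resolution: Optional[int] = 200  # None -> skip map rendering
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("ea", "grid"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.adjust not in ("none", "permute", "hpp"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")
        unknown = set(self.quadrant_names) - set(ALL_QUADRANTS)
        if unknown:
            raise ValueError(f"unknown quadrants {sorted(unknown)}")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class QuadrantResult:
    """Outcome of one quadrant: best coordinate, significance, label set.

    ``best`` is None (log_p 0, empty set) for an empty quadrant or one in
    which no coordinate shows the quadrant's expected sign.
    """

    quadrant: str
    best: Optional[BestCoordinate]
    p_adjusted: Optional[float] = None
    log_p_adjusted: Optional[float] = None
    beta_fit: Optional["hpp_adjust.BetaFit"] = None
    enriched_labels: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=object)
    )

    @property
    def log_p(self) -> float:
        return 0.0 if self.best is None else self.best.slp.log_p

    @property
    def sign(self) -> int:
        return +1 if self.best is None else self.best.slp.sign

    def summary(self) -> dict:
        return {
            "quadrant": self.quadrant,
            "best_i": None if self.best is None else self.best.i,
            "best_j": None if self.best is None else self.best.j,
            "overlap": None if self.best is None else self.best.overlap,
            "log_p": self.log_p,
            "sign": self.sign,
            "p_adjusted": self.p_adjusted,
            "log_p_adjusted": self.log_p_adjusted,
            "n_enriched": int(self.enriched_labels.size),
        }


@dataclass
class RRHOResult:
    """Full four-quadrant result with provenance."""

    quadrants: dict[str, QuadrantResult]
    overlap_map: Optional[OverlapMap]
    n: int
    config: RRHOConfig

    def summary(self) -> dict:
        return {
            "n": self.n,
            "config": self.config.to_dict(),
            "quadrants": {q: r.summary() for q, r in self.quadrants.items()},
        }


def quadrant_bounds(
    a: RankedList, b: RankedList, q: QuadrantSpec
) -> tuple[int, int]:
    """Maximal prefix lengths of a quadrant (0 means an empty quadrant)."""
    n = a.n
    if b.n != n:
        raise ValueError("lists must be aligned")
    max_i = a.split_index if q.orientation_a == "down" else n - a.split_index
    max_j = b.split_index if q.orientation_b == "down" else n - b.split_index
    return int(max_i), int(max_j)


def enrichment_set(
    a: RankedList, b: RankedList, q: QuadrantSpec, best: BestCoordinate
) -> np.ndarray:
    """Labels of the detected overlap at a quadrant's best coordinate."""
    frame = build_frame(a, b, q)
    if not (1 <= best.i <= max(frame.max_i, 1) and 1 <= best.j <= max(frame.max_j, 1)):
        raise ValueError(
            f"coordinate ({best.i}, {best.j}) outside quadrant bounds "
            f"({frame.max_i}, {frame.max_j})"
        )
    return frame.prefix_labels(best.i, best.j)


def _search_frame(
    frame: QuadrantFrame,
    q: QuadrantSpec,
    config: RRHOConfig,
    seed: int,
) -> Optional[BestCoordinate]:
    if config.algorithm == "grid":
        return grid_search_frame(frame, q, step=config.step, mode=config.mode)
    params = EAParams(
        generations=config.generations,
        population=config.population,
        elite_fraction=config.elite_fraction,
        mutation_scale=config.mutation_scale,
        mutation_prob=config.mutation_prob,
        seed=seed,
    )
    return ea_search_frame(frame, q, params=params, mode=config.mode)


def _quadrant_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence((seed, tag)).generate_state(1)[0] % (2**31))


def run_rrho(
    a: RankedList,
    b: RankedList,
    config: RRHOConfig = RRHOConfig(),
    expr_a=None,
    expr_b=None,
) -> RRHOResult:
    """Full overlap analysis: align, search each quadrant, extract sets,
    optionally adjust the minimal P-values by (hybrid) permutation.

    ``expr_a``/``expr_b`` are optional feature-by-sample log-expression
    DataFrames enabling the correlation-aware flavour of the adjustment
    (``config.adjust == "hpp"``).
    """
    a, b = align_lists(a, b)
    results: dict[str, QuadrantResult] = {}
    for qi, name in enumerate(config.quadrant_names):
        q = QUADRANTS[name]
        frame = build_frame(a, b, q)
        if frame.max_i < 1 or frame.max_j < 1:
            logger.info("quadrant %s is empty (zero extent)", name)
            results[name] = QuadrantResult(quadrant=name, best=None)
            continue
        best = _search_frame(frame, q, config, _quadrant_seed(config.seed, qi))
        if best is None:
            results[name] = QuadrantResult(quadrant=name, best=None)
            continue
        labels = frame.prefix_labels(best.i, best.j)
        results[name] = QuadrantResult(quadrant=name, best=best, enriched_labels=labels)

    if config.adjust != "none":
        hpp_adjust.adjust_results(
            a, b, results, config, expr_a=expr_a, expr_b=expr_b
        )

    overlap_map = None
    if config.render_resolution is not None:
        overlap_map = render_map(a, b, mode=config.mode,
                                 resolution=config.render_resolution)
    return RRHOResult(quadrants=results, overlap_map=overlap_map, n=a.n,
                      config=config)
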