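"""Reading, validation and orientation of ranked signatures.

A *ranked list* is a labelled vector of real-valued statistics (log fold
changes, signed P-values, slopes, ...).  Sorting it ascending puts the most
down-regulated features first; the position of the zero crossing (the count
of strictly negative values) is where the down- and up-regulated halves
meet, and anchors the four regulation quadrants downstream.

All coordinate conventions used by the rest of the package are defined
here:

* prefix coordinates are 1-based and inclusive: coordinate ``(i, j)``
  denotes the first ``i`` labels of one oriented list and the first ``j``
  of the other;
* ties in the statistic are broken by label lexicographic order so that
  every run is deterministic across platforms;
* a value of exactly 0 belongs to the up-regulated half.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Orientation = Literal["down", "up"]

__all__ = [
    "RankedList",
    "QuadrantSpec",
    "QUADRANTS",
    "read_ranked_list",
    "align_lists",
    "oriented_ranks",
]


@dataclass(frozen=True)
class RankedList:
    """A labelled, sortable vector of ranked statistics.

    Parameters
    ----------
    labels:
        Unique feature identifiers, in input order.
    values:
        The ranked statistic per label (same length as ``labels``).

    Attributes
    ----------
    order:
        Permutation of indices sorting ``values`` ascending (most
        down-regulated first), ties broken by label.
    split_index:
        Number of strictly negative values, i.e. the position of the zero
        crossing in the sorted order.
    """

    labels: np.ndarray
    values: np.ndarray
    order: np.ndarray = field(init=False, repr=False)
    split_index: int = field(init=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)
        if labels.ndim != 1 or values.ndim != 1:
            raise ValueError("labels and values must be one-dimensional")
        if labels.size != values.size:
            raise ValueError(
                f"labels ({labels.size}) and values ({values.size}) differ in length"
            )
        if labels.size < 2:
            raise ValueError("a ranked list needs at least 2 features")
        if not np.all(np.isfinite(values)):
            bad = np.flatnonzero(~np.isfinite(values))
            raise ValueError(
                f"non-finite statistic for labels {labels[bad[:5]].tolist()}"
            )
        uniq, counts = np.unique(labels.astype(str), return_counts=True)
        if uniq.size != labels.size:
            dups = uniq[counts > 1][:5].tolist()
            raise ValueError(f"duplicate labels: {dups}")
        # Stable sort on (value, label) keeps tied statistics deterministic.
        order = np.lexsort((labels.astype(str), values))
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "split_index", int(np.sum(values < 0.0)))

    @property
    def n(self) -> int:
        return int(self.labels.size)

    def sorted_labels(self) -> np.ndarray:
        """Labels in ascending-statistic (most down-regulated first) order."""
        return self.labels[self.order]

    def sorted_values(self) -> np.ndarray:
        return self.values[self.order]

    def rank_of(self) -> dict:
        """Map label -> 0-based position in the down-oriented order."""
        return {lab: k for k, lab in enumerate(self.sorted_labels())}


@dataclass(frozen=True)
class QuadrantSpec:
    """One of the four regulation-direction quadrants.

    ``orientation_a``/``orientation_b`` say from which extremity of each
    list the quadrant's prefixes grow; correlated quadrants (dd, uu) expect
    enrichment of the joint prefix, anticorrelated ones (du, ud) expect
    the corresponding depletion signal (negative sign).
    """

    name: str
    orientation_a: Orientation
    orientation_b: Orientation

    @property
    def anticorrelated(self) -> bool:
        return self.orientation_a != self.orientation_b

    @property
    def sign_expectation(self) -> int:
        """Expected sign of the reported P-value: +1 for dd/uu, -1 for du/ud."""
        return -1 if self.anticorrelated else +1


QUADRANTS: dict[str, QuadrantSpec] = {
    "dd": QuadrantSpec("dd", "down", "down"),
    "uu": QuadrantSpec("uu", "up", "up"),
    "du": QuadrantSpec("du", "down", "up"),
    "ud": QuadrantSpec("ud", "up", "down"),
}


def read_ranked_list(
    path, id_column: str = "id", value_column: str = "value"
) -> RankedList:
    """Read a TSV differential-analysis table into a :class:`RankedList`.

    The file must have a header naming both columns.  Gzipped input is
    accepted (by extension).  Duplicate identifiers, missing columns and
    non-numeric or NaN statistics raise ``ValueError``.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        table = pd.read_csv(fh, sep="\t", dtype={0: str})
    for col in (id_column, value_column):
        if col not in table.columns:
            raise ValueError(
                f"column {col!r} not found in {path} (have {list(table.columns)})"
            )
    raw = table[value_column]
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"non-numeric or missing statistic at data row {row + 1} "
            f"of {path} (value {raw.iloc[row]!r})"
        )
    labels = table[id_column].astype(str).to_numpy(dtype=object)
    return RankedList(labels=labels, values=numeric.to_numpy(dtype=float))


def align_lists(a: RankedList, b: RankedList) -> tuple[RankedList, RankedList]:
    """Restrict both lists to their common label universe.

    Returns the inputs unchanged when the label sets are identical;
    otherwise drops the non-shared labels (warning through the module
    logger) and rebuilds both lists.  Raises on an empty intersection.
    """
    set_a = set(a.labels.tolist())
    set_b = set(b.labels.tolist())
    if set_a == set_b:
        return a, b
    common = set_a & set_b
    if not common:
        raise ValueError("the two ranked lists share no labels")
    dropped_a = len(set_a) - len(common)
    dropped_b = len(set_b) - len(common)
    logger.warning(
        "aligning ranked lists: dropped %d labels from a and %d from b "
        "(%d shared labels kept)",
        dropped_a,
        dropped_b,
        len(common),
    )
    keep_a = np.fromiter((lab in common for lab in a.labels), bool, a.n)
    keep_b = np.fromiter((lab in common for lab in b.labels), bool, b.n)
    return (
        RankedList(labels=a.labels[keep_a], values=a.values[keep_a]),
        RankedList(labels=b.labels[keep_b], values=b.values[keep_b]),
    )


def oriented_ranks(ranked: RankedList, orientation: Orientation) -> np.ndarray:
    """Labels ordered from the requested extremity.

    ``down`` puts the most down-regulated feature first; ``up`` is exactly
    the reverse.  A prefix of length ``i`` of the result is "the top *i*
    features from that extremity".
    """
    if orientation == "down":
        return ranked.sorted_labels()
    if orientation == "up":
        return ranked.sorted_labels()[::-1]
    raise ValueError(f"unknown orientation {orientation!r}")


def oriented_positions(ranked: RankedList, orientation: Orientation) -> np.ndarray:
    """0-based position of every feature (in ``labels`` order) counted from
    the requested extremity; feature k is inside the oriented prefix of
    length i iff ``oriented_positions(...)[k] < i``."""
    pos = np.empty(ranked.n, dtype=np.int64)
    pos[ranked.order] = np.arange(ranked.n)
    if orientation == "up":
        pos = ranked.n - 1 - pos
    return pos
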