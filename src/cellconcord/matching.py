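"""Gated one-to-one correspondence between two annotation sets.

Cells from two sources are put in correspondence by building the
Euclidean distance matrix between their centers, solving a minimum-cost
bipartite assignment, and accepting only pairs closer than a distance
gate (default 25 px, the radius of an average cell at 0.23 um/px).

By default the gate is applied *before* solving: distances above the
gate are replaced by a forbidden cost, so the solver returns the
maximum-cardinality gate-feasible matching of minimum total distance.
Post-filtering a global assignment (``pregate=False``) is also offered:
there, the ungated optimum is computed first and pairs beyond the gate
are dissolved afterwards, which can discard pairs a feasible matching
would have kept.

From a match the 4x4 extended confusion matrix over
{tumor, cd3_positive, non_specified, missing} is tallied; the extra
"missing" row/column holds cells present in only one of the two sets and
is what the missing-data kappa variants operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .records import REAL_LABELS, AnnotationSet, CellLabel

__all__ = ["MatchResult", "ExtendedConfusionMatrix", "match_sets", "confusion_from_match"]

#: Index of the "missing" class on the extended confusion-matrix axes.
MISSING_INDEX = 3

_LABEL_INDEX = {label: i for i, label in enumerate(REAL_LABELS)}
_LABEL_INDEX[CellLabel.DIVERSE] = None  # diverse cells never enter the ECM


@dataclass(frozen=True)
class MatchResult:
    """A gated one-to-one correspondence between two sets.

    ``pairs`` holds ``(left_index, right_index, distance)`` triples; every
    left and right index appears exactly once across ``pairs`` and the
    respective unmatched list, and every pair distance is <= ``gate``.
    """

    pairs: tuple[tuple[int, int, float], ...]
    unmatched_left: tuple[int, ...]
    unmatched_right: tuple[int, ...]
    gate: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def transpose(self) -> "MatchResult":
        """Swap the roles of left and right."""
        return MatchResult(
            pairs=tuple(sorted((j, i, d) for i, j, d in self.pairs)),
            unmatched_left=self.unmatched_right,
            unmatched_right=self.unmatched_left,
            gate=self.gate,
        )


@dataclass
class ExtendedConfusionMatrix:
    """4x4 counts over {tumor, cd3_positive, non_specified, missing}.

    Axis order follows :data:`cellconcord.records.REAL_LABELS` with
    "missing" last; rows index the left source, columns the right.  The
    (missing, missing) entry is structurally zero: a cell absent from
    both sets does not exist.
    """

    counts: np.ndarray
    left_source: str = ""
    right_source: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValidationError(
                f"extended confusion matrix must be 4x4, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValidationError("confusion counts must be non-negative")
        if self.counts[MISSING_INDEX, MISSING_INDEX] != 0:
            raise ValidationError("(missing, missing) count must be zero")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def core(self) -> np.ndarray:
        """The 3x3 block over the real classes."""
        return self.counts[:3, :3]

    def transpose(self) -> "ExtendedConfusionMatrix":
        return ExtendedConfusionMatrix(
            counts=self.counts.T.copy(),
            left_source=self.right_source,
            right_source=self.left_source,
        )

    def __add__(self, other: "ExtendedConfusionMatrix") -> "ExtendedConfusionMatrix":
        return ExtendedConfusionMatrix(
            counts=self.counts + other.counts,
            left_source=self.left_source,
            right_source=self.right_source,
        )


def match_sets(
    left: AnnotationSet,
    right: AnnotationSet,
    gate: float = 25.0,
    pregate: bool = True,
) -> MatchResult:
    """Optimal gated one-to-one correspondence between two sets.

    Parameters
    ----------
    left, right
        The two annotation sets; either may be empty.
    gate
        Maximum center distance in pixels for two cells to be considered
        the same cell.
    pregate
        If True (default), distances above the gate are forbidden before
        the assignment is solved, yielding the maximum-cardinality
        gate-feasible matching of minimum total distance.  If False, the
        ungated global optimum is solved first and out-of-gate pairs are
        dissolved afterwards.

    Returns
    -------
    MatchResult
        Pairs sorted by left index; unmatched indices in ascending order.
    """
    if gate <= 0:
        raise ValidationError(f"gate must be positive, got {gate}")

    n_left, n_right = len(left), len(right)
    if n_left == 0 or n_right == 0:
        return MatchResult(
            pairs=(),
            unmatched_left=tuple(range(n_left)),
            unmatched_right=tuple(range(n_right)),
            gate=gate,
        )

    distances = cdist(left.centers(), right.centers())
    if pregate:
        # Forbidden cost exceeds any achievable total of in-gate pairs, so
        # the solver first maximizes the number of in-gate pairs, then
        # minimizes their summed distance.
        forbidden = gate * (min(n_left, n_right) + 1.0) + 1.0
        cost = np.where(distances <= gate, distances, forbidden)
    else:
        cost = distances

    row_ind, col_ind = linear_sum_assignment(cost)

    pairs = []
    matched_left = np.zeros(n_left, dtype=bool)
    matched_right = np.zeros(n_right, dtype=bool)
    for i, j in zip(row_ind, col_ind):
        if distances[i, j] <= gate:
            pairs.append((int(i), int(j), float(distances[i, j])))
            matched_left[i] = True
            matched_right[j] = True
    pairs.sort()
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_left=tuple(int(i) for i in np.flatnonzero(~matched_left)),
        unmatched_right=tuple(int(j) for j in np.flatnonzero(~matched_right)),
        gate=gate,
    )


def confusion_from_match(
    left: AnnotationSet,
    right: AnnotationSet,
    match: MatchResult,
) -> ExtendedConfusionMatrix:
    """Tally the 4x4 extended confusion matrix from a match.

    Matched pair (i, j) increments ``counts[label_i, label_j]``; a cell
    unmatched on the left increments its label's "missing" column entry,
    and vice versa.  Diverse-labeled cells must be filtered out by the
    caller before matching.
    """
    counts = np.zeros((4, 4), dtype=np.int64)

    def index_of(label: CellLabel, side: str) -> int:
        idx = _LABEL_INDEX[label]
        if idx is None:
            raise ValidationError(
                f"diverse-labeled cell in {side} set: exclude diverse cells "
                "before building a confusion matrix"
            )
        return idx

    for i, j, _ in match.pairs:
        if i >= len(left) or j >= len(right):
            raise ValidationError(
                f"match pair ({i}, {j}) out of range for sets of size "
                f"{len(left)} and {len(right)}"
            )
        counts[index_of(left[i].label, "left"), index_of(right[j].label, "right")] += 1
    for i in match.unmatched_left:
        if i >= len(left):
            raise ValidationError(f"unmatched left index {i} out of range")
        counts[index_of(left[i].label, "left"), MISSING_INDEX] += 1
    for j in match.unmatched_right:
        if j >= len(right):
            raise ValidationError(f"unmatched right index {j} out of range")
        counts[MISSING_INDEX, index_of(right[j].label, "right")] += 1

    return ExtendedConfusionMatrix(
        counts=counts,
        left_source=left.source_id,
        right_source=right.source_id,
    )
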