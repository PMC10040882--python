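"""Multi-rater consensus annotations.

Under the assumption that raters rarely hallucinate cells, the consensus
contains every cell annotated by any rater.  Cells reported by several
raters are merged into one consensus cell whose label is decided by
majority vote; when no strict plurality exists — typically a cell
annotated by exactly two raters who assigned different labels — the
consensus cell receives the special "diverse" label.  Diverse cells are
conventionally excluded from downstream evaluations.

The raters never state which of their cells are "the same cell", so a
clustering rule is needed.  Cells are clustered by greedy agglomeration:
all cross-rater cell pairs closer than the gate (default 25 px) are
visited in ascending distance order, and the two clusters containing the
endpoints are merged when (a) no rater contributes to both and (b) every
cross-cluster member pair is within the gate (complete linkage, so
chains cannot stretch a cluster beyond one cell diameter).  The result
depends only on cell positions, not on rater names or input order; ties
at exactly equal distance are broken by position and finally by source
id.  No cluster ever holds two cells of the same rater.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import UndefinedStatisticError, ValidationError
from .records import AnnotationSet, CellLabel, CellRecord

__all__ = ["ConsensusCell", "build_consensus", "build_consensus_cells", "diverse_fraction"]

CONSENSUS_SOURCE_ID = "consensus"


@dataclass
class ConsensusCell:
    """One consensus cluster.

    ``member_refs`` lists the contributing ``(source_id, cell_index)``
    pairs; ``support`` is their count.  ``label`` is diverse exactly when
    the member labels have no strict plurality.
    """

    center: tuple[float, float]
    label: CellLabel
    support: int
    member_refs: list[tuple[str, int]]
    member_labels: list[CellLabel]


def _majority_label(labels: Sequence[CellLabel]) -> CellLabel:
    votes = Counter(labels)
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return CellLabel.DIVERSE  # draw: no strict plurality
    return ranked[0][0]


def build_consensus_cells(
    sets: Sequence[AnnotationSet],
    gate: float = 25.0,
) -> list[ConsensusCell]:
    """Cluster the raters' cells; full bookkeeping variant.

    See the module docstring for the rule.  Returns one
    :class:`ConsensusCell` per cluster, ordered by the first appearance
    of a member cell when iterating raters in source-id order.
    """
    if len(sets) < 2:
        raise ValidationError("consensus needs at least two annotation sets")
    roi_ids = {s.roi_id for s in sets}
    if len(roi_ids) != 1:
        raise ValidationError(f"sets span several ROIs: {sorted(roi_ids)}")
    source_ids = [s.source_id for s in sets]
    if len(set(source_ids)) != len(source_ids):
        raise ValidationError(f"duplicate source_ids: {sorted(source_ids)}")
    if gate <= 0:
        raise ValidationError(f"gate must be positive, got {gate}")

    ordered = sorted(sets, key=lambda s: s.source_id)
    # flat arrays over all cells of all raters
    sources: list[str] = []
    indices: list[int] = []
    labels: list[CellLabel] = []
    points: list[tuple[float, float]] = []
    rater_of: list[int] = []
    for r, rater in enumerate(ordered):
        for i, cell in enumerate(rater.cells):
            sources.append(rater.source_id)
            indices.append(i)
            labels.append(cell.label)
            points.append(cell.center)
            rater_of.append(r)

    n = len(points)
    if n == 0:
        return []
    coords = np.asarray(points, dtype=float)

    # candidate merges: cross-rater pairs within the gate, nearest first
    tree = cKDTree(coords)
    candidate_pairs = tree.query_pairs(gate, output_type="ndarray")
    edges = []
    for a, b in candidate_pairs:
        a, b = int(a), int(b)
        if rater_of[a] == rater_of[b]:
            continue
        d = float(np.hypot(*(coords[a] - coords[b])))
        edges.append((d, tuple(coords[min(a, b)]), tuple(coords[max(a, b)]),
                      sources[a], indices[a], a, b))
    edges.sort()

    # union-find with per-cluster rater sets for the exclusion constraint
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    raters: dict[int, set[int]] = {i: {rater_of[i]} for i in range(n)}

    for d, _, _, _, _, a, b in edges:
        ra, rb = find(a), find(b)
        if ra == rb or raters[ra] & raters[rb]:
            continue
        # complete linkage: every cross-cluster pair must respect the gate
        if any(
            np.hypot(*(coords[u] - coords[v])) > gate
            for u in members[ra]
            for v in members[rb]
        ):
            continue
        parent[rb] = ra
        members[ra].extend(members.pop(rb))
        raters[ra] |= raters.pop(rb)

    # emit clusters ordered by first appearance in rater order
    clusters: dict[int, list[int]] = {}
    order: list[int] = []
    for i in range(n):
        root = find(i)
        if root not in clusters:
            clusters[root] = members[root]
            order.append(root)

    out = []
    for root in order:
        idx = clusters[root]
        pts = coords[idx]
        out.append(
            ConsensusCell(
                center=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                label=_majority_label([labels[i] for i in idx]),
                support=len(idx),
                member_refs=[(sources[i], indices[i]) for i in idx],
                member_labels=[labels[i] for i in idx],
            )
        )
    return out


def build_consensus(
    sets: Sequence[AnnotationSet],
    gate: float = 25.0,
) -> AnnotationSet:
    """Consensus annotation set: union of raters, majority labels, diverse ties."""
    cells = [
        CellRecord(
            center_x=cc.center[0],
            center_y=cc.center[1],
            label=cc.label,
            source_id=CONSENSUS_SOURCE_ID,
        )
        for cc in build_consensus_cells(sets, gate=gate)
    ]
    return AnnotationSet(
        roi_id=sets[0].roi_id, source_id=CONSENSUS_SOURCE_ID, cells=cells
    )


def diverse_fraction(consensus: AnnotationSet) -> float:
    """Fraction of consensus cells labeled diverse, on one ROI."""
    if len(consensus) == 0:
        raise UndefinedStatisticError("diverse fraction undefined on an empty consensus")
    return consensus.count(CellLabel.DIVERSE) / len(consensus)
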