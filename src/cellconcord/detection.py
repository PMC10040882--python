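"""Scoring detections against a reference annotation.

Detections are matched to reference cells with the same gated Hungarian
correspondence used for inter-rater agreement.  From the correspondence,
per-class true positives (matched, same class), false negatives
(reference cells unmatched or matched to another predicted class) and
false positives (detections unmatched — "hallucinated" cells — or
matched to another reference class) are tallied.  Sweeping the detection
score threshold yields precision-recall pairs, summarized by the average
precision (AP): each precision is weighted by the recall increase to the
next threshold.  The default sweep uses the 11 thresholds 0.0, 0.1, ...,
1.0.

Diverse-labeled reference cells (consensus ties) are excluded from the
evaluation entirely, together with any detection matched to them —
such detections count neither as true nor as false positives.

Also here: greedy non-maximum suppression (NMS) for merging detections
from overlapping inference patches or from model ensembles, the
patch-grid stitcher, and class-ratio counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import UndefinedStatisticError, ValidationError
from .matching import ExtendedConfusionMatrix, confusion_from_match, match_sets
from .records import REAL_LABELS, AnnotationSet, CellLabel, CellRecord

__all__ = [
    "ClassCounts",
    "PRPoint",
    "APResult",
    "evaluate_detections",
    "average_precision",
    "mean_average_precision",
    "nms_merge",
    "stitch_patch_detections",
    "class_ratio",
]


@dataclass(frozen=True)
class ClassCounts:
    """TP/FP/FN for one class at one threshold."""

    label: CellLabel
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        """tp / (tp + fp); 1.0 when there are no detections (empty-claim convention)."""
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else 0.0


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class APResult:
    class_label: CellLabel
    ap: float
    points: tuple[PRPoint, ...]


def _filter_diverse(
    reference: AnnotationSet,
    detections: AnnotationSet,
    gate: float,
) -> tuple[AnnotationSet, AnnotationSet]:
    """Drop diverse reference cells and the detections matched to them.

    The match used for this exclusion is computed on the full sets so a
    detection 'claimed' by a diverse consensus cell cannot be counted as
    a false positive against some other cell afterwards.
    """
    if reference.count(CellLabel.DIVERSE) == 0:
        return reference, detections
    match = match_sets(reference, detections, gate=gate)
    diverse_ref = {
        i for i, c in enumerate(reference.cells) if c.label is CellLabel.DIVERSE
    }
    claimed = {j for i, j, _ in match.pairs if i in diverse_ref}
    kept_ref = [i for i in range(len(reference)) if i not in diverse_ref]
    kept_det = [j for j in range(len(detections)) if j not in claimed]
    return reference.subset(kept_ref), detections.subset(kept_det)


def evaluate_detections(
    reference: AnnotationSet,
    detections: AnnotationSet,
    gate: float = 25.0,
    threshold: float = 0.0,
) -> tuple[dict[CellLabel, ClassCounts], ExtendedConfusionMatrix]:
    """Per-class TP/FP/FN and the extended confusion matrix at one threshold.

    Detections with score below ``threshold`` are discarded; diverse
    reference cells and detections matched to them are excluded; the
    remaining sets are matched with the gated assignment.
    """
    scores = detections.scores()  # raises if any detection lacks a score
    kept = [i for i in range(len(detections)) if scores[i] >= threshold]
    detections = detections.subset(kept)
    reference, detections = _filter_diverse(reference, detections, gate)

    match = match_sets(reference, detections, gate=gate)
    ecm = confusion_from_match(reference, detections, match)

    counts: dict[CellLabel, ClassCounts] = {}
    for k, label in enumerate(REAL_LABELS):
        tp = int(ecm.counts[k, k])
        fn = int(ecm.counts[k, :].sum() - tp)   # other predicted class or missed
        fp = int(ecm.counts[:, k].sum() - tp)   # other reference class or unannotated
        counts[label] = ClassCounts(label=label, tp=tp, fp=fp, fn=fn)
    return counts, ecm


def average_precision(
    reference: AnnotationSet,
    detections: AnnotationSet,
    class_label: CellLabel,
    gate: float = 25.0,
    thresholds: Optional[Sequence[float]] = None,
) -> APResult:
    """Average precision for one class over a detection-threshold sweep.

    By default the 11 thresholds 0.0, 0.1, ..., 1.0 are used; pass
    ``thresholds="unique"`` semantics by supplying the sorted unique
    scores explicitly.  At each threshold sigma, detections with score
    strictly above sigma are kept, so the top of the sweep contributes
    the empty-detection anchor (recall 0, precision 1) and the bottom
    keeps every scored detection.  Points are ordered by increasing
    recall and AP sums each precision weighted by the recall increase to
    the next point.

    Raises
    ------
    UndefinedStatisticError
        If the reference contains no (non-diverse) cell of the class —
        recall, and hence AP, has no meaning there.
    """
    if class_label not in REAL_LABELS:
        raise ValidationError(f"AP is defined for real classes, not {class_label}")
    scores = detections.scores()
    reference, detections = _filter_diverse(reference, detections, gate)
    scores = detections.scores()
    if reference.count(class_label) == 0:
        raise UndefinedStatisticError(
            f"AP undefined: reference has no {class_label.value} cells"
        )
    if thresholds is None:
        thresholds = np.round(np.linspace(0.0, 1.0, 11), 10)

    points = []
    for sigma in thresholds:
        kept = detections.subset(list(np.flatnonzero(scores > sigma)))
        counts, _ = evaluate_detections(reference, kept, gate=gate, threshold=0.0)
        c = counts[class_label]
        points.append(
            PRPoint(
                threshold=float(sigma),
                precision=c.precision,
                recall=c.recall,
                tp=c.tp,
                fp=c.fp,
                fn=c.fn,
            )
        )

    # increasing recall == decreasing threshold; stable for exact ties
    points.sort(key=lambda p: (p.recall, -p.threshold))
    ap = sum(
        (points[k + 1].recall - points[k].recall) * points[k].precision
        for k in range(len(points) - 1)
    )
    return APResult(class_label=class_label, ap=float(ap), points=tuple(points))


def mean_average_precision(
    reference: AnnotationSet,
    detections: AnnotationSet,
    gate: float = 25.0,
    thresholds: Optional[Sequence[float]] = None,
) -> tuple[float, dict[CellLabel, APResult]]:
    """Mean AP over the classes present in the reference.

    Classes absent from the reference are reported as absent, not as 0.
    """
    per_class: dict[CellLabel, APResult] = {}
    for label in REAL_LABELS:
        try:
            per_class[label] = average_precision(
                reference, detections, label, gate=gate, thresholds=thresholds
            )
        except UndefinedStatisticError:
            continue
    if not per_class:
        raise UndefinedStatisticError("mAP undefined: reference is empty")
    return float(np.mean([r.ap for r in per_class.values()])), per_class


def nms_merge(detections: Sequence[AnnotationSet], radius: float) -> AnnotationSet:
    """Greedy non-maximum suppression on centroids.

    Repeatedly keeps the highest-score remaining detection (ties broken
    by source id, then position, for determinism) and suppresses every
    other detection, of any source, within ``radius`` pixels.  Output is
    sorted by descending score.
    """
    if radius < 0:
        raise ValidationError(f"radius must be non-negative, got {radius}")
    if not detections:
        raise ValidationError("nms_merge needs at least one detection set")
    roi_ids = {s.roi_id for s in detections}
    if len(roi_ids) != 1:
        raise ValidationError(f"sets span several ROIs: {sorted(roi_ids)}")

    cells: list[CellRecord] = []
    for s in detections:
        for c in s.cells:
            if c.score is None:
                raise ValidationError(f"unscored detection in set {s.source_id!r}")
            cells.append(c)
    if not cells:
        return AnnotationSet(roi_id=detections[0].roi_id, source_id="nms", cells=[])

    order = sorted(
        range(len(cells)),
        key=lambda i: (-cells[i].score, cells[i].source_id, cells[i].center_x, cells[i].center_y),
    )
    centers = np.array([c.center for c in cells], dtype=float)
    dist = cdist(centers, centers)
    suppressed = np.zeros(len(cells), dtype=bool)
    keep: list[int] = []
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        suppressed[dist[i] <= radius] = True
    return AnnotationSet(
        roi_id=detections[0].roi_id,
        source_id="nms",
        cells=[
            CellRecord(
                center_x=cells[i].center_x,
                center_y=cells[i].center_y,
                label=cells[i].label,
                source_id="nms",
                box=cells[i].box,
                score=cells[i].score,
            )
            for i in keep
        ],
    )


def stitch_patch_detections(
    patch_results: Sequence[tuple[tuple[float, float], AnnotationSet]],
    patch_size: float = 256.0,
    overlap: float = 128.0,
    nms_radius: float = 25.0,
) -> AnnotationSet:
    """Merge patch-local detections into one ROI-frame set.

    Patches of side ``patch_size`` are assumed to tile the ROI with the
    given ``overlap`` (stride = patch_size - overlap); detections carry
    patch-local coordinates and are translated by their patch origin,
    concatenated, then de-duplicated with :func:`nms_merge`.
    """
    if not patch_results:
        raise ValidationError("no patches to stitch")
    stride = patch_size - overlap
    if stride <= 0:
        raise ValidationError("overlap must be smaller than patch_size")
    translated: list[AnnotationSet] = []
    for (ox, oy), patch_set in patch_results:
        if abs(ox % stride) > 1e-6 or abs(oy % stride) > 1e-6:
            raise ValidationError(
                f"patch origin ({ox}, {oy}) is off the stride-{stride} grid"
            )
        cells = []
        for idx, c in enumerate(patch_set.cells):
            if not (0 <= c.center_x <= patch_size and 0 <= c.center_y <= patch_size):
                raise ValidationError(
                    f"detection {idx} at ({c.center_x}, {c.center_y}) lies outside "
                    f"its {patch_size}x{patch_size} patch"
                )
            box = c.box
            if box is not None:
                box = (box[0] + ox, box[1] + oy, box[2] + ox, box[3] + oy)
            cells.append(
                CellRecord(
                    center_x=c.center_x + ox,
                    center_y=c.center_y + oy,
                    label=c.label,
                    source_id=patch_set.source_id,
                    box=box,
                    score=c.score,
                )
            )
        translated.append(
            AnnotationSet(
                roi_id=patch_set.roi_id, source_id=patch_set.source_id, cells=cells
            )
        )
    return nms_merge(translated, radius=nms_radius)


def class_ratio(
    annotation_set: AnnotationSet,
    numerator: CellLabel,
    denominator: CellLabel,
) -> float:
    """Count ratio between two classes, e.g. CD3+ over non-specified.

    Pool across ROIs by summing counts before dividing.
    """
    denom = annotation_set.count(denominator)
    if denom == 0:
        raise UndefinedStatisticError(
            f"ratio undefined: no {denominator.value} cells in the set"
        )
    return annotation_set.count(numerator) / denom
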