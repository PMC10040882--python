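"""Chance-corrected inter-rater agreement with missed cells.

Two raters who annotate the same ROI disagree for two distinct reasons:
they assign different labels to the same cell, or one of them misses the
cell entirely.  Plain Cohen's kappa only sees the first kind.  This
module computes Cohen's kappa together with three adaptations for
missing annotations (after De Raadt et al.):

* **Regular Category** — missed cells form a fourth class; kappa is
  computed on the full 4x4 extended matrix, so omissions depress both
  observed agreement and the chance correction.
* **Listwise Deletion** — only cells labeled by both raters enter the
  computation; omissions are ignored.
* **Gwet** — observed agreement over jointly labeled cells as in
  listwise deletion, but singly-labeled cells still inflate the expected
  agreement denominator.

All statistics operate on the 4x4 extended confusion matrix produced by
:func:`cellconcord.matching.confusion_from_match`; axis order is
(tumor, cd3_positive, non_specified, missing).

Kappa is always ``(Po - Pe) / (1 - Pe)``.  Interpretation follows the
Landis-Koch intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .matching import ExtendedConfusionMatrix, confusion_from_match, match_sets
from .records import AnnotationSet, CellLabel

__all__ = [
    "KappaVariant",
    "AgreementStrength",
    "KappaResult",
    "kappa_standard",
    "kappa_regular_category",
    "kappa_listwise_deletion",
    "kappa_gwet",
    "interpret_kappa",
    "pairwise_agreement_report",
]


class KappaVariant(str, Enum):
    STANDARD = "standard"
    REGULAR_CATEGORY = "regular_category"
    LISTWISE_DELETION = "listwise_deletion"
    GWET = "gwet"


class AgreementStrength(str, Enum):
    """Landis-Koch interpretation bands for kappa."""

    POOR = "poor"
    SLIGHT = "slight"
    FAIR = "fair"
    MODERATE = "moderate"
    SUBSTANTIAL = "substantial"
    ALMOST_PERFECT = "almost_perfect"


@dataclass(frozen=True)
class KappaResult:
    variant: KappaVariant
    po: float
    pe: float
    kappa: float
    interpretation: AgreementStrength
    n_effective: int  #: number of cells entering the observed agreement

    def __post_init__(self) -> None:
        if self.kappa > 1.0 + 1e-12:
            raise ValidationError(f"kappa {self.kappa} exceeds 1")


def interpret_kappa(kappa: float) -> AgreementStrength:
    """Map a kappa value to its Landis-Koch band.

    Intervals are left-open as usually stated: kappa < 0 poor,
    (0, 0.2] slight, (0.2, 0.4] fair, (0.4, 0.6] moderate,
    (0.6, 0.8] substantial, (0.8, 1.0] almost perfect.  Exactly 0 is
    assigned to slight.
    """
    if kappa > 1.0 + 1e-12:
        raise ValidationError(f"kappa {kappa} exceeds 1")
    if kappa < 0:
        return AgreementStrength.POOR
    if kappa <= 0.2:
        return AgreementStrength.SLIGHT
    if kappa <= 0.4:
        return AgreementStrength.FAIR
    if kappa <= 0.6:
        return AgreementStrength.MODERATE
    if kappa <= 0.8:
        return AgreementStrength.SUBSTANTIAL
    return AgreementStrength.ALMOST_PERFECT


def _finish(variant: KappaVariant, po: float, pe: float, n_effective: int) -> KappaResult:
    if pe >= 1.0:
        raise UndefinedStatisticError(
            f"{variant.value} kappa undefined: expected agreement is 1"
        )
    kappa = (po - pe) / (1.0 - pe)
    return KappaResult(
        variant=variant,
        po=po,
        pe=pe,
        kappa=kappa,
        interpretation=interpret_kappa(kappa),
        n_effective=n_effective,
    )


def _as_counts(cm, shape: tuple[int, int]) -> np.ndarray:
    counts = np.asarray(cm, dtype=float)
    if counts.shape != shape:
        raise ValidationError(f"expected a {shape} count matrix, got {counts.shape}")
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    return counts


def kappa_standard(cm: Union[np.ndarray, Sequence[Sequence[int]]]) -> KappaResult:
    """Cohen's kappa on a plain 3x3 confusion matrix.

    Po is the fraction of cells on the diagonal; Pe the chance agreement
    from the row and column margins.
    """
    counts = _as_counts(cm, (3, 3))
    total = counts.sum()
    if total == 0:
        raise UndefinedStatisticError("standard kappa undefined: no cells")
    po = np.trace(counts) / total
    pe = float(counts.sum(axis=1) @ counts.sum(axis=0)) / total**2
    return _finish(KappaVariant.STANDARD, float(po), pe, int(total))


def _ecm_counts(ecm: Union[ExtendedConfusionMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(ecm, ExtendedConfusionMatrix):
        return ecm.counts.astype(float)
    return _as_counts(ecm, (4, 4))


def kappa_regular_category(
    ecm: Union[ExtendedConfusionMatrix, np.ndarray],
) -> KappaResult:
    """Kappa with "missing" as a fourth class, on the full 4x4 matrix.

    Because a cell absent from both sets does not exist, the
    (missing, missing) cell is structurally zero, so missingness can
    only lower Po relative to the jointly-labeled core and shift mass
    into the margins of Pe.
    """
    counts = _ecm_counts(ecm)
    total = counts.sum()
    if total == 0:
        raise UndefinedStatisticError("regular-category kappa undefined: no cells")
    po = np.trace(counts) / total  # includes the structurally zero (t, t) cell
    pe = float(counts.sum(axis=1) @ counts.sum(axis=0)) / total**2
    return _finish(KappaVariant.REGULAR_CATEGORY, float(po), pe, int(total))


def kappa_listwise_deletion(
    ecm: Union[ExtendedConfusionMatrix, np.ndarray],
) -> KappaResult:
    """Kappa restricted to cells labeled by both raters.

    Both Po and Pe are computed from the 3x3 jointly-labeled core; the
    margins subtract each class's missing counts.
    """
    counts = _ecm_counts(ecm)
    core = counts[:3, :3]
    n_joint = core.sum()
    if n_joint == 0:
        raise UndefinedStatisticError(
            "listwise-deletion kappa undefined: no jointly labeled cells"
        )
    po = np.trace(core) / n_joint
    row_margins = counts[:3, :].sum(axis=1) - counts[:3, 3]
    col_margins = counts[:, :3].sum(axis=0) - counts[3, :3]
    pe = float(row_margins @ col_margins) / n_joint**2
    return _finish(KappaVariant.LISTWISE_DELETION, float(po), pe, int(n_joint))


def kappa_gwet(ecm: Union[ExtendedConfusionMatrix, np.ndarray]) -> KappaResult:
    """Gwet's adaptation: listwise Po, but Pe keeps singly-labeled cells.

    Pe uses the full row/column margins of the real classes over
    ``(N - n_t.) * (N - n_.t)``, where ``n_t.`` and ``n_.t`` count cells
    each rater missed.
    """
    counts = _ecm_counts(ecm)
    core = counts[:3, :3]
    n_joint = core.sum()
    if n_joint == 0:
        raise UndefinedStatisticError("Gwet kappa undefined: no jointly labeled cells")
    total = counts.sum()
    miss_row = counts[3, :].sum()  # cells only the right rater labeled
    miss_col = counts[:, 3].sum()  # cells only the left rater labeled
    if total - miss_row <= 0 or total - miss_col <= 0:
        raise UndefinedStatisticError("Gwet kappa undefined: a rater labeled no cells")
    po = np.trace(core) / n_joint
    row_margins = counts[:3, :].sum(axis=1)
    col_margins = counts[:, :3].sum(axis=0)
    pe = float(row_margins @ col_margins) / ((total - miss_row) * (total - miss_col))
    return _finish(KappaVariant.GWET, float(po), pe, int(n_joint))


_VARIANT_FUNCS = {
    KappaVariant.REGULAR_CATEGORY: kappa_regular_category,
    KappaVariant.LISTWISE_DELETION: kappa_listwise_deletion,
    KappaVariant.GWET: kappa_gwet,
}


def kappa_all_variants(
    ecm: Union[ExtendedConfusionMatrix, np.ndarray],
) -> dict[KappaVariant, KappaResult]:
    """All four variants on one extended matrix.

    The standard variant is evaluated on the jointly-labeled 3x3 core.
    Variants that are undefined for the given matrix are omitted.
    """
    counts = _ecm_counts(ecm)
    out: dict[KappaVariant, KappaResult] = {}
    try:
        out[KappaVariant.STANDARD] = kappa_standard(counts[:3, :3])
    except UndefinedStatisticError:
        pass
    for variant, func in _VARIANT_FUNCS.items():
        try:
            out[variant] = func(counts)
        except UndefinedStatisticError:
            pass
    return out


def pairwise_agreement_report(
    sets: Sequence[AnnotationSet],
    gate: float = 25.0,
    pooled: bool = True,
) -> pd.DataFrame:
    """Kappa table for every unique pair of sources.

    ``sets`` may span several ROIs; sources are identified by
    ``source_id``.  Diverse-labeled cells are excluded before matching.
    With ``pooled=True`` confusion counts are summed across ROIs before
    computing kappa (micro-averaging); otherwise one row per ROI and
    pair is emitted.

    Returns a DataFrame with columns ``roi_id`` (or "pooled"),
    ``source_a``, ``source_b``, ``variant``, ``po``, ``pe``, ``kappa``,
    ``interpretation``, ``n_effective``.
    """
    if len(sets) < 2:
        raise ValidationError("need at least two annotation sets")
    by_roi: dict[str, dict[str, AnnotationSet]] = {}
    for s in sets:
        roi = by_roi.setdefault(s.roi_id, {})
        if s.source_id in roi:
            raise ValidationError(
                f"duplicate source {s.source_id!r} on ROI {s.roi_id!r}"
            )
        roi[s.source_id] = s

    sources = sorted({s.source_id for s in sets})
    rows = []

    def emit(roi_label: str, a: str, b: str, ecm: ExtendedConfusionMatrix) -> None:
        for variant, result in kappa_all_variants(ecm).items():
            rows.append(
                {
                    "roi_id": roi_label,
                    "source_a": a,
                    "source_b": b,
                    "variant": variant.value,
                    "po": result.po,
                    "pe": result.pe,
                    "kappa": result.kappa,
                    "interpretation": result.interpretation.value,
                    "n_effective": result.n_effective,
                }
            )

    for a, b in itertools.combinations(sources, 2):
        pooled_ecm: ExtendedConfusionMatrix | None = None
        for roi_id in sorted(by_roi):
            roi_sets = by_roi[roi_id]
            if a not in roi_sets or b not in roi_sets:
                continue
            left = roi_sets[a].without_label(CellLabel.DIVERSE)
            right = roi_sets[b].without_label(CellLabel.DIVERSE)
            ecm = confusion_from_match(left, right, match_sets(left, right, gate=gate))
            if pooled:
                pooled_ecm = ecm if pooled_ecm is None else pooled_ecm + ecm
            else:
                emit(roi_id, a, b, ecm)
        if pooled and pooled_ecm is not None:
            emit("pooled", a, b, pooled_ecm)

    return pd.DataFrame(
        rows,
        columns=[
            "roi_id", "source_a", "source_b", "variant",
            "po", "pe", "kappa", "interpretation", "n_effective",
        ],
    )
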