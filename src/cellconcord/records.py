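"""Typed data model for annotated and detected cells.

A :class:`CellRecord` is one cell as reported by one source (a human
rater, semi-automatic annotation software, a detector, or a consensus
procedure).  An :class:`AnnotationSet` is the ordered collection of all
cells of one source on one region of interest (ROI).

Coordinates are 0-based pixel coordinates with the origin at the top-left
corner, x growing rightward and y downward; bounding boxes are closed
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["CellLabel", "CellRecord", "AnnotationSet", "REAL_LABELS"]


class CellLabel(str, Enum):
    """Cell classes.

    ``TUMOR`` and ``CD3_POSITIVE`` are individually annotated classes;
    ``NON_SPECIFIED`` collects the remaining (unstained stromal) cells.
    ``DIVERSE`` marks consensus cells on which raters tied without a
    plurality; it never appears in single-rater or detector sets.
    """

    TUMOR = "tumor"
    CD3_POSITIVE = "cd3_positive"
    NON_SPECIFIED = "non_specified"
    DIVERSE = "diverse"

    @classmethod
    def from_string(cls, value: str) -> "CellLabel":
        try:
            return cls(value.strip().lower())
        except ValueError:
            raise ValidationError(f"unknown cell label {value!r}") from None


#: The three real cell classes, in canonical order (confusion-matrix axes).
REAL_LABELS: tuple[CellLabel, ...] = (
    CellLabel.TUMOR,
    CellLabel.CD3_POSITIVE,
    CellLabel.NON_SPECIFIED,
)


@dataclass(frozen=True)
class CellRecord:
    """One annotated or detected cell.

    Parameters
    ----------
    center_x, center_y
        Cell center in pixels, >= 0.
    label
        Cell class.
    source_id
        Identifier of the producing source (rater, software, detector).
    box
        Optional bounding box ``(min_x, min_y, max_x, max_y)``; when
        present the center must equal the box centroid to within 0.5 px.
    score
        Detection score in [0, 1]; present iff the record is a detection.
    """

    center_x: float
    center_y: float
    label: CellLabel
    source_id: str
    box: Optional[tuple[float, float, float, float]] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.center_x < 0 or self.center_y < 0:
            raise ValidationError(
                f"cell center ({self.center_x}, {self.center_y}) has a "
                "negative coordinate"
            )
        if self.box is not None:
            min_x, min_y, max_x, max_y = self.box
            if not (min_x < max_x and min_y < max_y):
                raise ValidationError(f"degenerate bounding box {self.box}")
            cx, cy = (min_x + max_x) / 2.0, (min_y + max_y) / 2.0
            if abs(cx - self.center_x) > 0.5 or abs(cy - self.center_y) > 0.5:
                raise ValidationError(
                    f"center ({self.center_x}, {self.center_y}) is more than "
                    f"0.5 px from box centroid ({cx}, {cy})"
                )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        return (self.center_x, self.center_y)

    @classmethod
    def from_box(
        cls,
        box: tuple[float, float, float, float],
        label: CellLabel,
        source_id: str,
        score: Optional[float] = None,
    ) -> "CellRecord":
        """Build a record from box vertices; the center is the centroid."""
        min_x, min_y, max_x, max_y = box
        return cls(
            center_x=(min_x + max_x) / 2.0,
            center_y=(min_y + max_y) / 2.0,
            label=label,
            source_id=source_id,
            box=box,
            score=score,
        )

    @classmethod
    def from_point(
        cls,
        center_x: float,
        center_y: float,
        label: CellLabel,
        source_id: str,
        box_side: float = 50.0,
        score: Optional[float] = None,
    ) -> "CellRecord":
        """Build a record from a one-click center annotation.

        A square box of side ``box_side`` (default 50 px, i.e. +-25 px,
        the radius of an average cell) is synthesized around the center.
        """
        half = box_side / 2.0
        return cls(
            center_x=center_x,
            center_y=center_y,
            label=label,
            source_id=source_id,
            box=(center_x - half, center_y - half, center_x + half, center_y + half),
            score=score,
        )


@dataclass
class AnnotationSet:
    """All cells of one source on one ROI, in stable order."""

    roi_id: str
    source_id: str
    cells: list[CellRecord] = field(default_factory=list)
    roi_width: Optional[float] = None
    roi_height: Optional[float] = None

    def __post_init__(self) -> None:
        for i, cell in enumerate(self.cells):
            if cell.source_id != self.source_id:
                raise ValidationError(
                    f"cell {i} has source_id {cell.source_id!r}, "
                    f"set has {self.source_id!r}"
                )
            if self.roi_width is not None and cell.center_x > self.roi_width:
                raise ValidationError(
                    f"cell {i} center_x {cell.center_x} exceeds ROI width "
                    f"{self.roi_width}"
                )
            if self.roi_height is not None and cell.center_y > self.roi_height:
                raise ValidationError(
                    f"cell {i} center_y {cell.center_y} exceeds ROI height "
                    f"{self.roi_height}"
                )

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[CellRecord]:
        return iter(self.cells)

    def __getitem__(self, index: int) -> CellRecord:
        return self.cells[index]

    def centers(self) -> np.ndarray:
        """Cell centers as an (n, 2) float array."""
        if not self.cells:
            return np.empty((0, 2), dtype=float)
        return np.array([(c.center_x, c.center_y) for c in self.cells], dtype=float)

    def labels(self) -> list[CellLabel]:
        return [c.label for c in self.cells]

    def scores(self) -> np.ndarray:
        """Detection scores; raises if any cell lacks one."""
        out = np.empty(len(self.cells), dtype=float)
        for i, c in enumerate(self.cells):
            if c.score is None:
                raise ValidationError(
                    f"cell {i} of source {self.source_id!r} has no score"
                )
            out[i] = c.score
        return out

    def count(self, label: CellLabel) -> int:
        return sum(1 for c in self.cells if c.label is label)

    def subset(self, indices: Sequence[int]) -> "AnnotationSet":
        """New set with the cells at ``indices``, order preserved."""
        return AnnotationSet(
            roi_id=self.roi_id,
            source_id=self.source_id,
            cells=[self.cells[i] for i in indices],
            roi_width=self.roi_width,
            roi_height=self.roi_height,
        )

    def without_label(self, label: CellLabel) -> "AnnotationSet":
        return self.subset(
            [i for i, c in enumerate(self.cells) if c.label is not label]
        )

    def with_source_id(self, source_id: str) -> "AnnotationSet":
        """Copy of the set re-attributed to ``source_id``."""
        return AnnotationSet(
            roi_id=self.roi_id,
            source_id=source_id,
            cells=[replace(c, source_id=source_id) for c in self.cells],
            roi_width=self.roi_width,
            roi_height=self.roi_height,
        )
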