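"""Readers and writers for the CSV annotation dialects.

Two dialects are supported, mirroring how cell annotations are exported
in practice:

* ``box`` — one row per cell with bounding-box vertices, as exported by
  annotation software: columns ``roi_id, source_id, min_x, min_y, max_x,
  max_y, label, score`` (``score`` blank for plain annotations).
  Optional ``center_x, center_y`` columns carry the exact cell center;
  without them the box midpoint is used.
* ``point`` — one-click center annotations: columns ``roi_id, source_id,
  center_x, center_y, label``.  On read, a square box of configurable
  side (default 50 px, i.e. center +- 25 px) is synthesized around each
  center.

Files are UTF-8, comma-separated, ``.`` decimal separator, header
mandatory.  Reading back a written file reproduces the set field for
field.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Union

import pandas as pd

from .errors import FormatError, IOError_, ValidationError
from .records import AnnotationSet, CellLabel, CellRecord

__all__ = ["read_annotation_csv", "write_annotation_csv"]

_BOX_COLUMNS = [
    "roi_id", "source_id", "min_x", "min_y", "max_x", "max_y",
    "center_x", "center_y", "label", "score",
]
_POINT_COLUMNS = ["roi_id", "source_id", "center_x", "center_y", "label"]

Dialect = Literal["box", "point"]


def _parse_float(value, column: str, row: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: non-numeric value {value!r} in column {column!r}"
        ) from None
    if math.isnan(out):
        raise ValidationError(f"row {row}: missing value in column {column!r}")
    return out


def read_annotation_csv(
    path: Union[str, Path],
    dialect: Dialect = "box",
    point_box_side: float = 50.0,
) -> AnnotationSet:
    """Read one annotation set from a CSV file.

    Parameters
    ----------
    path
        CSV file holding the cells of a single source on a single ROI.
    dialect
        ``"box"`` for bounding-box rows, ``"point"`` for center-click rows.
    point_box_side
        Side length of the square box synthesized around point
        annotations.  The default of 50 px corresponds to +-25 px, the
        radius of an average cell at 0.23 um/px.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If a label string or coordinate cannot be parsed (the message
        names the offending row).
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"file not found: {path}")
    if dialect not in ("box", "point"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    required = _BOX_COLUMNS if dialect == "box" else _POINT_COLUMNS

    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, header row required") from None

    for column in required:
        if column in ("score", "center_x", "center_y") and dialect == "box":
            continue  # optional: absent in files written by other tools
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    has_score = "score" in frame.columns
    has_center = "center_x" in frame.columns and "center_y" in frame.columns

    cells: list[CellRecord] = []
    roi_id = ""
    source_id = ""
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        record = row._asdict()
        roi_id = record["roi_id"]
        source_id = record["source_id"]
        label = CellLabel.from_string(record["label"])
        score = None
        if has_score and record.get("score", "") != "":
            score = _parse_float(record["score"], "score", row_number)
        try:
            if dialect == "box":
                box = tuple(
                    _parse_float(record[c], c, row_number)
                    for c in ("min_x", "min_y", "max_x", "max_y")
                )
                if has_center and record["center_x"] != "" and record["center_y"] != "":
                    # explicit center wins: exact round-trips, while the box
                    # midpoint can drift by a float ulp
                    cells.append(
                        CellRecord(
                            center_x=_parse_float(record["center_x"], "center_x", row_number),
                            center_y=_parse_float(record["center_y"], "center_y", row_number),
                            label=label,
                            source_id=source_id,
                            box=box,
                            score=score,
                        )
                    )
                else:
                    cells.append(CellRecord.from_box(box, label, source_id, score=score))
            else:
                cx = _parse_float(record["center_x"], "center_x", row_number)
                cy = _parse_float(record["center_y"], "center_y", row_number)
                cells.append(
                    CellRecord.from_point(
                        cx, cy, label, source_id, box_side=point_box_side, score=score
                    )
                )
        except ValidationError as exc:
            raise ValidationError(f"row {row_number}: {exc}") from None

    if len(frame) == 0:
        # header-only file: identity comes from the caller's file naming
        roi_id, source_id = path.stem, path.stem
    return AnnotationSet(roi_id=roi_id, source_id=source_id, cells=cells)


def write_annotation_csv(annotation_set: AnnotationSet, path: Union[str, Path]) -> Path:
    """Write a set in the box dialect; inverse of :func:`read_annotation_csv`.

    Cells without a stored box get one synthesized around their center
    (side 50 px) so the file is always valid box-dialect.
    """
    path = Path(path)
    rows = []
    for cell in annotation_set.cells:
        box = cell.box
        if box is None:
            box = (
                cell.center_x - 25.0,
                cell.center_y - 25.0,
                cell.center_x + 25.0,
                cell.center_y + 25.0,
            )
        rows.append(
            {
                "roi_id": annotation_set.roi_id,
                "source_id": annotation_set.source_id,
                "min_x": repr(box[0]),
                "min_y": repr(box[1]),
                "max_x": repr(box[2]),
                "max_y": repr(box[3]),
                "center_x": repr(cell.center_x),
                "center_y": repr(cell.center_y),
                "label": cell.label.value,
                "score": "" if cell.score is None else repr(cell.score),
            }
        )
    frame = pd.DataFrame(rows, columns=_BOX_COLUMNS)
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise IOError_(f"cannot write {path}: {exc}") from None
    return path
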