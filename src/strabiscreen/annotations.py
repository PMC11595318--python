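"""Pupil-annotation readers and writers.

Three dialects are supported:

* ``native_csv`` — the package's canonical form: one CSV row per image with
  full-frame, 0-based pixel coordinates (columns ``image_path``,
  ``left_pupil_x/y``, ``right_pupil_y/x``; empty cells mean "no annotation
  for that eye").
* ``json`` — the same records as a JSON list.
* ``gi4e_txt`` (read-only) — the plain-text dialect used by periocular
  benchmark sets: one line per image, an image filename followed by twelve
  whitespace-separated numbers (six x,y landmark points, three per eye).
  Which of the six points are the pupil centres varies between releases, so
  the point-role mapping is configurable; the default takes points 1 and 4
  (0-based, i.e. the middle point of each triplet) as the left and right
  pupils with the first triplet belonging to the left eye.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import AnnotationError

DIALECTS = ("native_csv", "gi4e_txt", "json")

_CSV_COLUMNS = ["image_path", "left_pupil_x", "left_pupil_y", "right_pupil_x", "right_pupil_y"]


@dataclass(frozen=True)
class AnnotationRecord:
    """One image's pupil annotations in full-frame pixel coordinates."""

    image_path: str
    left_pupil: tuple[float, float] | None
    right_pupil: tuple[float, float] | None
    source_dialect: str = "native_csv"

    def __post_init__(self) -> None:
        for name, p in (("left_pupil", self.left_pupil), ("right_pupil", self.right_pupil)):
            if p is not None and (p[0] < 0 or p[1] < 0):
                raise AnnotationError(f"{name} has negative coordinates: {p}")


def read_annotations(
    path: str | Path,
    dialect: str = "native_csv",
    pupil_point_indices: tuple[int, int] = (1, 4),
    first_triplet: str = "left",
) -> list[AnnotationRecord]:
    """Parse an annotation file into records; malformed lines are reported
    with their line numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native_csv":
        return _read_native_csv(path)
    if dialect == "json":
        return _read_json(path)
    if dialect == "gi4e_txt":
        return _read_gi4e(path, pupil_point_indices, first_triplet)
    raise AnnotationError(f"unknown dialect {dialect!r}; supported: {list(DIALECTS)}")


def _opt_point(x, y) -> tuple[float, float] | None:
    if pd.isna(x) or pd.isna(y):
        return None
    return float(x), float(y)


def _read_native_csv(path: Path) -> list[AnnotationRecord]:
    table = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in table.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    records = []
    for rec in table.itertuples():
        records.append(
            AnnotationRecord(
                image_path=str(rec.image_path),
                left_pupil=_opt_point(rec.left_pupil_x, rec.left_pupil_y),
                right_pupil=_opt_point(rec.right_pupil_x, rec.right_pupil_y),
                source_dialect="native_csv",
            )
        )
    return records


def _read_json(path: Path) -> list[AnnotationRecord]:
    data = json.loads(path.read_text())
    records = []
    for i, d in enumerate(data):
        try:
            records.append(
                AnnotationRecord(
                    image_path=d["image_path"],
                    left_pupil=tuple(d["left_pupil"]) if d.get("left_pupil") else None,
                    right_pupil=tuple(d["right_pupil"]) if d.get("right_pupil") else None,
                    source_dialect="json",
                )
            )
        except (KeyError, TypeError) as exc:
            raise AnnotationError(f"{path}: bad record at index {i}: {exc}") from exc
    return records


def _read_gi4e(
    path: Path, pupil_point_indices: tuple[int, int], first_triplet: str
) -> list[AnnotationRecord]:
    if first_triplet not in ("left", "right"):
        raise AnnotationError("first_triplet must be 'left' or 'right'")
    i_first, i_second = pupil_point_indices
    records = []
    bad: list[int] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 13:
            bad.append(lineno)
            continue
        try:
            nums = [float(v) for v in parts[1:]]
        except ValueError:
            bad.append(lineno)
            continue
        points = [(nums[2 * i], nums[2 * i + 1]) for i in range(6)]
        first, second = points[i_first], points[i_second]
        left, right = (first, second) if first_triplet == "left" else (second, first)
        records.append(
            AnnotationRecord(
                image_path=parts[0],
                left_pupil=left,
                right_pupil=right,
                source_dialect="gi4e_txt",
            )
        )
    if bad:
        raise AnnotationError(
            f"{path}: malformed annotation lines (expected a filename plus 12 "
            f"numbers) at line(s) {bad}"
        )
    return records


def write_annotations(
    records: Sequence[AnnotationRecord], path: str | Path, dialect: str = "native_csv"
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "native_csv":
        rows = []
        for r in records:
            rows.append(
                dict(
                    image_path=r.image_path,
                    left_pupil_x=r.left_pupil[0] if r.left_pupil else None,
                    left_pupil_y=r.left_pupil[1] if r.left_pupil else None,
                    right_pupil_x=r.right_pupil[0] if r.right_pupil else None,
                    right_pupil_y=r.right_pupil[1] if r.right_pupil else None,
                )
            )
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
        return path
    if dialect == "json":
        data = [
            dict(
                image_path=r.image_path,
                left_pupil=list(r.left_pupil) if r.left_pupil else None,
                right_pupil=list(r.right_pupil) if r.right_pupil else None,
            )
            for r in records
        ]
        path.write_text(json.dumps(data, indent=2))
        return path
    raise AnnotationError(
        f"cannot write dialect {dialect!r}; writable: ['native_csv', 'json']"
    )
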