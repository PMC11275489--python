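"""Readers and writers for the pipeline's plain-text exchange formats.

Formats (all CSV/JSON, documented column-by-column):

* frames — JSON list (or CSV) of per-image geometry:
  ``image_id, width_px, height_px, fovea_x, fovea_y, disc_x, disc_y,
  fov_deg[, um_per_px, laterality]``.
* marks — CSV of lesion annotations/detections:
  ``image_id, lesion_type, x_px, y_px, diameter_um[, mean_intensity]``.
* counts — CSV, one row per image x region:
  ``image_id, region, n_MA, n_HEM``.
* grades — CSV: ``image_id, mu_a, h, nv, level, label``.
* report — long-format summaries CSV + a JSON block with ANOVA/t results.

Writing then reading a table reproduces the records exactly; malformed rows
are rejected with their file line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import FundusFrame, Laterality, QuadrantCounts, Region
from .grading import DRGrade
from .lesions import LesionMark, LesionType, coerce_lesion_type
from .stats import CohortReport


class ParseError(ValueError):
    """A malformed row, reported with its source line."""

    def __init__(self, path: str | Path, line: int | None, message: str):
        where = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{where}: {message}")
        self.path, self.line = str(path), line


_FRAME_FIELDS = ["image_id", "width_px", "height_px", "fovea_x", "fovea_y", "disc_x", "disc_y", "fov_deg"]
_MARK_FIELDS = ["image_id", "lesion_type", "x_px", "y_px", "diameter_um"]


def _require_columns(df: pd.DataFrame, required: list[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing column(s) {missing}")


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------


def _frame_from_record(rec: Mapping, path: str | Path, line: int | None) -> FundusFrame:
    try:
        return FundusFrame(
            image_id=str(rec["image_id"]),
            width_px=int(rec["width_px"]),
            height_px=int(rec["height_px"]),
            fovea_x=float(rec["fovea_x"]),
            fovea_y=float(rec["fovea_y"]),
            disc_x=float(rec["disc_x"]),
            disc_y=float(rec["disc_y"]),
            fov_deg=float(rec.get("fov_deg", 45.0)),
            um_per_px=(float(rec["um_per_px"]) if rec.get("um_per_px") not in (None, "") else None),
            laterality=Laterality(rec.get("laterality", "unknown") or "unknown"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(path, line, f"bad frame record: {exc}") from exc


def read_frames(path: str | Path) -> dict[str, FundusFrame]:
    """Read frame metadata (JSON ``.json`` or CSV), keyed by image id."""
    path = Path(path)
    frames: dict[str, FundusFrame] = {}
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = payload["frames"] if isinstance(payload, dict) else payload
        for i, rec in enumerate(records):
            frame = _frame_from_record(rec, path, i)
            frames[frame.image_id] = frame
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        _require_columns(df, _FRAME_FIELDS, path)
        for i, rec in enumerate(df.to_dict("records")):
            frame = _frame_from_record(rec, path, i + 2)  # +2: header + 1-based
            frames[frame.image_id] = frame
    return frames


def write_frames(frames: Iterable[FundusFrame] | Mapping[str, FundusFrame], path: str | Path) -> None:
    path = Path(path)
    if isinstance(frames, Mapping):
        frames = frames.values()
    records = [
        {
            "image_id": f.image_id,
            "width_px": f.width_px,
            "height_px": f.height_px,
            "fovea_x": f.fovea_x,
            "fovea_y": f.fovea_y,
            "disc_x": f.disc_x,
            "disc_y": f.disc_y,
            "fov_deg": f.fov_deg,
            "um_per_px": f.um_per_px,
            "laterality": f.laterality.value,
        }
        for f in frames
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"frames": records}, indent=1, sort_keys=True) + "\n")
    else:
        pd.DataFrame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Marks
# ---------------------------------------------------------------------------


def read_marks(path: str | Path) -> dict[str, list[LesionMark]]:
    """Read a lesion-mark CSV, grouped by image id (order preserved)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _MARK_FIELDS, path)
    out: dict[str, list[LesionMark]] = {}
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2
        try:
            lesion = coerce_lesion_type(rec["lesion_type"])
        except ValueError as exc:
            raise ParseError(path, line, str(exc)) from exc
        try:
            mi = rec.get("mean_intensity")
            mark = LesionMark(
                lesion_type=lesion,
                x_px=float(rec["x_px"]),
                y_px=float(rec["y_px"]),
                diameter_um=float(rec["diameter_um"]),
                mean_intensity=None if mi is None or (isinstance(mi, float) and np.isnan(mi)) else float(mi),
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(path, line, f"bad mark record: {exc}") from exc
        out.setdefault(str(rec["image_id"]), []).append(mark)
    return out


def write_marks(marks: Mapping[str, Iterable[LesionMark]], path: str | Path) -> None:
    rows = [
        {
            "image_id": image_id,
            "lesion_type": m.lesion_type.value,
            "x_px": m.x_px,
            "y_px": m.y_px,
            "diameter_um": m.diameter_um,
            "mean_intensity": m.mean_intensity,
        }
        for image_id, ms in marks.items()
        for m in ms
    ]
    pd.DataFrame(rows, columns=_MARK_FIELDS + ["mean_intensity"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Counts, grades, report
# ---------------------------------------------------------------------------


def write_counts(counts: Iterable[QuadrantCounts] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(counts, pd.DataFrame):
        df = counts
    else:
        df = pd.DataFrame([row for qc in counts for row in qc.to_rows()])
    df.to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Long-format per-image region counts (image_id, region, n_MA, n_HEM)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["image_id", "region", "n_MA", "n_HEM"], path)
    valid = {r.value for r in Region}
    for i, region in enumerate(df["region"]):
        if region not in valid:
            raise ParseError(path, i + 2, f"unknown region {region!r}")
    df["image_id"] = df["image_id"].astype(str)
    return df


def write_grades(grades: Mapping[str, DRGrade], path: str | Path) -> None:
    rows = [
        {"image_id": image_id, "mu_a": g.mu_a, "h": g.h, "nv": g.nv, "level": g.level, "label": g.label}
        for image_id, g in grades.items()
    ]
    pd.DataFrame(rows, columns=["image_id", "mu_a", "h", "nv", "level", "label"]).to_csv(path, index=False)


def read_grades(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["image_id", "level"], path)
    df["image_id"] = df["image_id"].astype(str)
    return df


def write_report(report: CohortReport, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``report_summaries.csv`` and ``report_stats.json``; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = out_dir / "report_summaries.csv"
    stats_json = out_dir / "report_stats.json"
    report.summaries.to_csv(summaries, index=False)
    stats_json.write_text(json.dumps(report.stats_dict(), indent=1, sort_keys=True) + "\n")
    return summaries, stats_json


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF raster as an RGB uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image)).save(path)
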