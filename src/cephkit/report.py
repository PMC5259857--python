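"""Landmark/measurement file I/O and the self-contained HTML case report.

File contracts
--------------
landmark CSV    header ``name,x,y``; one row per landmark, codes from the
                11-landmark registry.
landmark JSON   object mapping code -> [x, y], plus optional ``case_id``
                and ``image_size``.
measurement CSV ``name,kind,value,unit`` in canonical parameter order.
comparison CSV  the per-parameter agreement table (see evaluation module).

The HTML report is a single static document with inline styling — no
external assets — holding the linear table (mm), the angular table
(degrees), the calibration echo and file provenance.  Rendering is
deterministic given a frozen timestamp.
"""

from __future__ import annotations

import csv
import hashlib
import html
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

from .calibration import CalibrationSpec
from .errors import IncompleteReportError, LandmarkFileError, UnknownLandmarkError
from .geometry import Point2D
from .model import (
    LANDMARKS,
    PARAMETER_NAMES,
    LandmarkSet,
    MeasurementResult,
)

__all__ = [
    "CaseReport",
    "read_landmarks",
    "write_landmarks",
    "read_measurements_csv",
    "write_measurements_csv",
    "file_checksum",
    "build_case_report",
    "render_html_report",
]


def _parse_coord(raw, context: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise LandmarkFileError(f"{context}: cannot parse coordinate {raw!r}") from None
    return value


def _check_code(code: str, context: str) -> str:
    if code not in LANDMARKS:
        raise UnknownLandmarkError(f"{context}: unknown landmark code {code!r}")
    return code


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark set from a ``.csv`` or ``.json`` coordinate file."""
    path = Path(path)
    if not path.exists():
        raise LandmarkFileError(f"landmark file not found: {path}")
    if path.suffix.lower() == ".csv":
        return _read_landmarks_csv(path)
    if path.suffix.lower() == ".json":
        return _read_landmarks_json(path)
    raise LandmarkFileError(f"unsupported landmark file extension: {path.suffix!r}")


def _read_landmarks_csv(path: Path) -> LandmarkSet:
    points = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != ["name", "x", "y"]:
            raise LandmarkFileError(
                f"{path}: expected header 'name,x,y', got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            code = _check_code((row["name"] or "").strip(), f"{path}:{lineno}")
            points[code] = Point2D(
                _parse_coord(row["x"], f"{path}:{lineno}"),
                _parse_coord(row["y"], f"{path}:{lineno}"),
            )
    return LandmarkSet(points=points, case_id=path.stem)


def _read_landmarks_json(path: Path) -> LandmarkSet:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LandmarkFileError(f"{path}: invalid JSON ({exc})") from None
    if not isinstance(payload, dict):
        raise LandmarkFileError(f"{path}: expected a JSON object at top level")
    case_id = payload.pop("case_id", path.stem)
    image_size = payload.pop("image_size", None)
    if image_size is not None:
        image_size = tuple(int(v) for v in image_size)
    points = {}
    for code, xy in payload.items():
        _check_code(code, str(path))
        if not isinstance(xy, (list, tuple)) or len(xy) != 2:
            raise LandmarkFileError(f"{path}: key {code!r} must map to [x, y]")
        points[code] = Point2D(
            _parse_coord(xy[0], f"{path}:{code}"), _parse_coord(xy[1], f"{path}:{code}")
        )
    return LandmarkSet(points=points, case_id=str(case_id), image_size=image_size)


def write_landmarks(ls: LandmarkSet, path) -> None:
    """Write a landmark set as CSV or JSON, by extension, in registry order."""
    path = Path(path)
    ordered = [(c, ls.points[c]) for c in LANDMARKS if c in ls.points]
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x", "y"])
            for code, p in ordered:
                writer.writerow([code, repr(p.x), repr(p.y)])
    elif path.suffix.lower() == ".json":
        payload = {code: [p.x, p.y] for code, p in ordered}
        payload["case_id"] = ls.case_id
        if ls.image_size is not None:
            payload["image_size"] = list(ls.image_size)
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise LandmarkFileError(f"unsupported landmark file extension: {path.suffix!r}")


def write_measurements_csv(results: List[MeasurementResult], path) -> None:
    """Write measurement results as ``name,kind,value,unit`` rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "kind", "value", "unit"])
        for r in results:
            writer.writerow([r.name, r.kind, repr(r.value), r.unit])


def read_measurements_csv(path) -> List[MeasurementResult]:
    results = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            results.append(
                MeasurementResult(
                    name=row["name"], kind=row["kind"],
                    value=float(row["value"]), unit=row["unit"],
                )
            )
    return results


def file_checksum(path) -> str:
    """SHA-256 of a file's bytes, for provenance blocks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class CaseReport:
    """Everything the HTML case report renders."""

    case_id: str
    measurements: List[MeasurementResult]
    calibration: CalibrationSpec
    source_path: Optional[str] = None
    source_checksum: Optional[str] = None
    timestamp: str = "1970-01-01T00:00:00Z"

    def __post_init__(self) -> None:
        names = [m.name for m in self.measurements]
        if sorted(names) != sorted(PARAMETER_NAMES):
            missing = sorted(set(PARAMETER_NAMES) - set(names))
            extra = sorted(set(names) - set(PARAMETER_NAMES))
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise IncompleteReportError(
                f"report requires each of the 18 parameters exactly once; "
                f"missing={missing} extra={extra} duplicated={dupes}"
            )


def build_case_report(ls: LandmarkSet, measurements: List[MeasurementResult],
                      cal: CalibrationSpec, source_path=None,
                      timestamp: str = "1970-01-01T00:00:00Z") -> CaseReport:
    """Assemble a :class:`CaseReport`, hashing the source file if given."""
    checksum = file_checksum(source_path) if source_path else None
    return CaseReport(
        case_id=ls.case_id,
        measurements=measurements,
        calibration=cal,
        source_path=str(source_path) if source_path else None,
        source_checksum=checksum,
        timestamp=timestamp,
    )


_STYLE = (
    "body{font-family:sans-serif;margin:2em;color:#222}"
    "table{border-collapse:collapse;margin:1em 0}"
    "th,td{border:1px solid #999;padding:0.3em 0.8em;text-align:left}"
    "th{background:#eee}caption{font-weight:bold;margin-bottom:0.4em}"
    ".meta{color:#555;font-size:0.9em}"
)


def _table(caption: str, rows: List[MeasurementResult], unit: str) -> str:
    body = "".join(
        f"<tr><td>{html.escape(r.name)}</td><td>{r.value:.3f}</td>"
        f"<td>{html.escape(r.unit)}</td></tr>"
        for r in rows
    )
    return (
        f"<table><caption>{html.escape(caption)}</caption>"
        f"<tr><th>Parameter</th><th>Value</th><th>Unit</th></tr>{body}</table>"
    )


def render_html_report(report: CaseReport) -> str:
    """Render the case report as a self-contained HTML document."""
    linear = [m for m in report.measurements if m.kind == "linear"]
    angular = [m for m in report.measurements if m.kind == "angular"]
    provenance = ""
    if report.source_path:
        provenance = (
            f"<p class='meta'>Landmark file: {html.escape(report.source_path)}<br/>"
            f"SHA-256: {html.escape(report.source_checksum or '')}</p>"
        )
    return (
        "<!DOCTYPE html>\n"
        "<html lang='en'><head><meta charset='utf-8'/>"
        f"<title>Cephalometric report — {html.escape(report.case_id)}</title>"
        f"<style>{_STYLE}</style></head><body>"
        f"<h1>Cephalometric report — {html.escape(report.case_id)}</h1>"
        f"<p class='meta'>Generated {html.escape(report.timestamp)}</p>"
        f"{_table('Linear measurements (mm)', linear, 'mm')}"
        f"{_table('Angular measurements (degrees)', angular, 'deg')}"
        f"<p class='meta'>Calibration: {html.escape(report.calibration.describe())}</p>"
        f"{provenance}"
        "</body></html>\n"
    )
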