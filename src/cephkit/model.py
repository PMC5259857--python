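"""The cephalometric domain model and measurement engine.

A lateral-cephalogram analysis built on 11 hard-tissue landmarks, from
which 12 linear distances (reported in mm after calibration) and 6 angular
parameters (degrees, calibration-free) are derived.

Landmarks
---------
N (Nasion), S (Sella), Po (Porion), Or (Orbitale), Ar (Articulare),
Go (Gonion), Me (Menton), ANS / PNS (anterior / posterior nasal spine),
A (subspinale, "Point A"), B (supramentale, "Point B").

Angular constructions follow the standard textbook definitions:

* SNA, SNB — vertex angles at Nasion between the ray to Sella and the rays
  to points A and B; their signed difference ANB = SNA - SNB classifies the
  sagittal jaw relationship.
* NSAr (saddle angle) — vertex angle at Sella between the rays to Nasion
  and Articulare.
* FMA — the unsigned angle between the Frankfort horizontal (Po-Or) and
  the mandibular plane (Go-Me).
* PP-MP — the unsigned angle between the palatal plane (ANS-PNS) and the
  mandibular plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import math

from .calibration import CalibrationSpec, px_to_mm
from .errors import InvalidInputError, MissingLandmarkError
from .geometry import (
    AngleValue,
    LineSegment,
    Point2D,
    angle_at_vertex,
    angle_between_lines,
    distance_px,
)

__all__ = [
    "LANDMARKS",
    "LINEAR_DEFINITIONS",
    "ANGULAR_DEFINITIONS",
    "LandmarkSet",
    "MeasurementDefinition",
    "MeasurementResult",
    "ValidationReport",
    "registry",
    "validate_landmark_set",
    "measure_linear",
    "measure_angular",
    "measure_all",
]

#: The 11-landmark registry: code -> anatomical name.
LANDMARKS: Dict[str, str] = {
    "N": "Nasion",
    "S": "Sella",
    "Po": "Porion",
    "Or": "Orbitale",
    "Ar": "Articulare",
    "Go": "Gonion",
    "Me": "Menton",
    "ANS": "Anterior nasal spine",
    "PNS": "Posterior nasal spine",
    "A": "Point A (subspinale)",
    "B": "Point B (supramentale)",
}


@dataclass(frozen=True)
class MeasurementDefinition:
    """One named cephalometric parameter and its geometric construction.

    ``rule`` selects the construction:

    * ``segment`` — linear distance; operands are the two endpoint codes.
    * ``vertex-ray`` — angle at operands[0] between rays to operands[1]
      and operands[2].
    * ``line-pair`` — unsigned angle between lines (operands[0], operands[1])
      and (operands[2], operands[3]).
    * ``signed-difference`` — operands name two angular parameters whose
      signed difference is taken.
    """

    name: str
    kind: str  # "linear" | "angular"
    rule: str
    operands: Tuple[str, ...]

    def landmark_codes(self) -> Tuple[str, ...]:
        """Landmark codes this parameter ultimately depends on."""
        if self.rule == "signed-difference":
            by_name = {d.name: d for d in ANGULAR_DEFINITIONS}
            codes: List[str] = []
            for ref in self.operands:
                for c in by_name[ref].landmark_codes():
                    if c not in codes:
                        codes.append(c)
            return tuple(codes)
        return self.operands


def _seg(name: str) -> MeasurementDefinition:
    a, b = name.split("-")
    return MeasurementDefinition(name=name, kind="linear", rule="segment", operands=(a, b))


#: The 12 linear parameters, in canonical report order.
LINEAR_DEFINITIONS: List[MeasurementDefinition] = [
    _seg("Po-Or"),
    _seg("ANS-PNS"),
    _seg("Me-Go"),
    _seg("S-N"),
    _seg("N-A"),
    _seg("N-B"),
    _seg("N-Me"),
    _seg("N-ANS"),
    _seg("ANS-Me"),
    _seg("S-Go"),
    _seg("S-Ar"),
    _seg("Ar-Go"),
]

#: The 6 angular parameters, in canonical report order.
ANGULAR_DEFINITIONS: List[MeasurementDefinition] = [
    MeasurementDefinition("SNA", "angular", "vertex-ray", ("N", "S", "A")),
    MeasurementDefinition("SNB", "angular", "vertex-ray", ("N", "S", "B")),
    MeasurementDefinition("ANB", "angular", "signed-difference", ("SNA", "SNB")),
    MeasurementDefinition("FMA", "angular", "line-pair", ("Po", "Or", "Go", "Me")),
    MeasurementDefinition("PP-MP", "angular", "line-pair", ("ANS", "PNS", "Go", "Me")),
    MeasurementDefinition("NSAr", "angular", "vertex-ray", ("S", "N", "Ar")),
]

ALL_DEFINITIONS: List[MeasurementDefinition] = LINEAR_DEFINITIONS + ANGULAR_DEFINITIONS
PARAMETER_NAMES: List[str] = [d.name for d in ALL_DEFINITIONS]


@dataclass
class LandmarkSet:
    """Named landmark positions for one case, in image-pixel coordinates."""

    points: Dict[str, Point2D]
    case_id: str = "case"
    image_size: Optional[Tuple[int, int]] = None  # (width, height)

    def __post_init__(self) -> None:
        unknown = [c for c in self.points if c not in LANDMARKS]
        if unknown:
            raise InvalidInputError(
                f"unknown landmark code(s): {', '.join(sorted(unknown))}"
            )

    def missing(self) -> List[str]:
        return [c for c in LANDMARKS if c not in self.points]

    @property
    def complete(self) -> bool:
        return not self.missing()


@dataclass
class MeasurementResult:
    """One evaluated parameter: a distance in mm or an angle in degrees."""

    name: str
    kind: str
    value: float
    unit: str

    def __post_init__(self) -> None:
        expected = "mm" if self.kind == "linear" else "deg"
        if self.unit != expected:
            raise InvalidInputError(
                f"{self.kind} measurement must carry unit {expected!r}, got {self.unit!r}"
            )
        if self.kind == "linear" and self.value < 0:
            raise InvalidInputError("linear measurement cannot be negative")


@dataclass
class ValidationReport:
    """Findings from :func:`validate_landmark_set`; a report, not an exception."""

    missing: List[str] = field(default_factory=list)
    out_of_bounds: List[str] = field(default_factory=list)
    duplicates: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.missing

    @property
    def clean(self) -> bool:
        return not (self.missing or self.out_of_bounds or self.duplicates)


def registry() -> Tuple[List[MeasurementDefinition], List[str]]:
    """The full parameter registry: 18 definitions and the 11 landmark codes."""
    return list(ALL_DEFINITIONS), list(LANDMARKS)


def validate_landmark_set(ls: LandmarkSet) -> ValidationReport:
    """Check completeness, image bounds and coincident points."""
    report = ValidationReport(missing=ls.missing())
    if ls.image_size is not None:
        w, h = ls.image_size
        for code, p in ls.points.items():
            if not (0 <= p.x < w and 0 <= p.y < h):
                report.out_of_bounds.append(code)
    seen: Dict[Tuple[float, float], str] = {}
    for code in LANDMARKS:
        p = ls.points.get(code)
        if p is None:
            continue
        key = (p.x, p.y)
        if key in seen:
            report.duplicates.append((seen[key], code))
        else:
            seen[key] = code
    return report


def _require(ls: LandmarkSet, codes) -> None:
    absent = [c for c in codes if c not in ls.points]
    if absent:
        raise MissingLandmarkError(absent)


def measure_linear(ls: LandmarkSet, definition: MeasurementDefinition,
                   cal: CalibrationSpec) -> MeasurementResult:
    """Distance between the two operand landmarks, converted to mm."""
    if definition.kind != "linear":
        raise InvalidInputError(f"{definition.name} is not a linear parameter")
    _require(ls, definition.operands)
    a, b = (ls.points[c] for c in definition.operands)
    return MeasurementResult(
        name=definition.name,
        kind="linear",
        value=px_to_mm(distance_px(a, b), cal),
        unit="mm",
    )


def _vertex_angle(ls: LandmarkSet, operands: Tuple[str, ...]) -> AngleValue:
    v, e1, e2 = (ls.points[c] for c in operands)
    return angle_at_vertex(v, e1, e2)


def measure_angular(ls: LandmarkSet, definition: MeasurementDefinition) -> MeasurementResult:
    """One angular parameter in degrees; scale-invariant, so calibration-free."""
    if definition.kind != "angular":
        raise InvalidInputError(f"{definition.name} is not an angular parameter")
    _require(ls, definition.landmark_codes())
    if definition.rule == "vertex-ray":
        value = _vertex_angle(ls, definition.operands).degrees
    elif definition.rule == "line-pair":
        a1, a2, b1, b2 = (ls.points[c] for c in definition.operands)
        value = angle_between_lines(
            LineSegment(a1, a2), LineSegment(b1, b2)
        ).degrees
    elif definition.rule == "signed-difference":
        by_name = {d.name: d for d in ANGULAR_DEFINITIONS}
        first, second = (
            measure_angular(ls, by_name[ref]).value for ref in definition.operands
        )
        value = first - second
    else:  # pragma: no cover - registry is static
        raise InvalidInputError(f"unknown rule {definition.rule!r}")
    return MeasurementResult(name=definition.name, kind="angular", value=value, unit="deg")


def measure_all(ls: LandmarkSet, cal: CalibrationSpec) -> List[MeasurementResult]:
    """Evaluate all 18 parameters, 12 linear (mm) then 6 angular (deg).

    Requires a complete 11-landmark set; raises
    :class:`MissingLandmarkError` naming every absent code otherwise.
    """
    _require(ls, LANDMARKS)
    results = [measure_linear(ls, d, cal) for d in LINEAR_DEFINITIONS]
    results += [measure_angular(ls, d) for d in ANGULAR_DEFINITIONS]
    return results
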