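"""Planar geometry for landmark-based measurement.

Distances, slopes and angles between points and line segments expressed in
continuous image-pixel coordinates (origin top-left, x rightward, y
downward, 0-based).  All angle magnitudes are invariant under the y-axis
flip between image and mathematical conventions, so the same formulas
serve both.

Angles come in three flavours, tracked by :class:`AngleValue.kind`:

``vertex-ray``
    The angle at a vertex between two rays, in [0, 180] degrees.  This is
    the construction behind SNA, SNB and the saddle angle, whose clinical
    values routinely exceed 90 degrees.
``line-pair``
    The unsigned acute angle between two undirected lines, in [0, 90]
    degrees (FMA, palatal-mandibular angle).
``signed-difference``
    A signed difference of two named angles, in (-180, 180) degrees (ANB).

The textbook two-line angle formula ``atan((m1 - m2) / (1 + m1 m2))``
built from slopes is undefined for vertical lines and perpendicular pairs;
the implementations below use the atan2 of cross and dot products of
direction vectors, which agrees with the slope formula everywhere the
latter is defined and extends it continuously to the singular cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateSegmentError, InvalidInputError

__all__ = [
    "Point2D",
    "LineSegment",
    "AngleValue",
    "VERTICAL",
    "distance_px",
    "slope",
    "angle_between_lines",
    "angle_at_vertex",
    "rad_to_deg",
    "deg_to_rad",
]

_ANGLE_KINDS = ("vertex-ray", "line-pair", "signed-difference")


def _require_finite(value: float, what: str) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise InvalidInputError(f"{what} must be finite, got {value!r}")
    return v


@dataclass(frozen=True)
class Point2D:
    """A point in continuous image-pixel coordinates."""

    x: float
    y: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", _require_finite(self.x, "x coordinate"))
        object.__setattr__(self, "y", _require_finite(self.y, "y coordinate"))


@dataclass(frozen=True)
class LineSegment:
    """A segment between two points; slope/angle use require p1 != p2."""

    p1: Point2D
    p2: Point2D

    @property
    def is_degenerate(self) -> bool:
        return self.p1.x == self.p2.x and self.p1.y == self.p2.y

    def direction(self) -> tuple[float, float]:
        if self.is_degenerate:
            raise DegenerateSegmentError(
                f"segment endpoints coincide at ({self.p1.x}, {self.p1.y})"
            )
        return (self.p2.x - self.p1.x, self.p2.y - self.p1.y)


class _Vertical:
    """Marker returned by :func:`slope` for vertical segments."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "VERTICAL"


#: Distinguished slope of a vertical line (x2 == x1); never a raised ZeroDivisionError.
VERTICAL = _Vertical()


@dataclass(frozen=True)
class AngleValue:
    """An angle in degrees together with the convention it was measured under."""

    degrees: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _ANGLE_KINDS:
            raise InvalidInputError(f"unknown angle kind {self.kind!r}")
        d = _require_finite(self.degrees, "angle")
        lo, hi = {
            "vertex-ray": (0.0, 180.0),
            "line-pair": (0.0, 90.0),
            "signed-difference": (-180.0, 180.0),
        }[self.kind]
        if not (lo <= d <= hi):
            raise InvalidInputError(
                f"{self.kind} angle {d} outside [{lo}, {hi}] degrees"
            )
        object.__setattr__(self, "degrees", d)


def distance_px(a: Point2D, b: Point2D) -> float:
    """Euclidean distance between two points, in pixels.

    The hypotenuse of the coordinate differences: sqrt((x2-x1)^2 + (y2-y1)^2).
    """
    return math.hypot(b.x - a.x, b.y - a.y)


def slope(seg: LineSegment):
    """Slope (dy/dx) of a segment, or :data:`VERTICAL` when dx == 0.

    Raises
    ------
    DegenerateSegmentError
        If the endpoints coincide (no direction is defined).
    """
    dx, dy = seg.direction()
    if dx == 0.0:
        return VERTICAL
    return dy / dx


def _angle_between_directions(d1: tuple[float, float], d2: tuple[float, float],
                              undirected: bool) -> float:
    """Angle in degrees between two direction vectors via atan2(cross, dot).

    With ``undirected`` the vectors are treated as lines (result in [0, 90]);
    otherwise as rays (result in [0, 180]).
    """
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    dot = d1[0] * d2[0] + d1[1] * d2[1]
    if undirected:
        dot = abs(dot)
    return math.degrees(math.atan2(abs(cross), dot))


def angle_between_lines(l1: LineSegment, l2: LineSegment) -> AngleValue:
    """Unsigned acute angle between two undirected lines, in [0, 90] degrees.

    Exact for vertical lines and for perpendicular pairs (where the
    slope-based arctangent form has 1 + m1*m2 = 0); agrees with that form
    to rounding wherever it is defined.
    """
    deg = _angle_between_directions(l1.direction(), l2.direction(), undirected=True)
    return AngleValue(min(deg, 90.0), "line-pair")


def angle_at_vertex(vertex: Point2D, ray_end_1: Point2D, ray_end_2: Point2D) -> AngleValue:
    """Angle at ``vertex`` between the rays toward the two end points, [0, 180] deg.

    Invariant under rotation, translation and uniform scaling of the three
    points.  Raises :class:`DegenerateSegmentError` if either ray end
    coincides with the vertex.
    """
    r1 = LineSegment(vertex, ray_end_1).direction()
    r2 = LineSegment(vertex, ray_end_2).direction()
    deg = _angle_between_directions(r1, r2, undirected=False)
    return AngleValue(min(deg, 180.0), "vertex-ray")


def rad_to_deg(angle_rad: float) -> float:
    """Convert radians to degrees: rad / ((2*pi) / 360)."""
    return _require_finite(angle_rad, "angle") / ((2.0 * math.pi) / 360.0)


def deg_to_rad(angle_deg: float) -> float:
    """Inverse of :func:`rad_to_deg`."""
    return _require_finite(angle_deg, "angle") * ((2.0 * math.pi) / 360.0)
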