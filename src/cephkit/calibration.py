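"""Pixel-to-physical-length calibration.

Two calibration routes are supported:

* ``ppi`` mode: an effective pixel density (pixels per inch).  For a
  digitized film displayed at a known scale this can be derived from the
  ratio of image to screen pixel counts (:func:`compute_ppi`); distances
  convert as ``inches = pixels / ppi`` and then to millimetres via the
  exact 25.4 mm/inch.
* ``known-distance`` mode: a reference object of known physical length
  measured in pixels on the same image.  This is the clinically standard,
  assumption-free route and is exactly linear: ``mm = px * known_mm / known_px``.

Both routes agree whenever ``known_mm / known_px == 25.4 / ppi``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import math

from .errors import InvalidCalibrationError

__all__ = [
    "CalibrationSpec",
    "MM_PER_INCH",
    "compute_ppi",
    "px_to_inch",
    "px_to_mm",
    "mm_to_px",
]

MM_PER_INCH = 25.4


def _positive(value: float, what: str) -> float:
    v = float(value)
    if not math.isfinite(v) or v <= 0:
        raise InvalidCalibrationError(f"{what} must be positive and finite, got {value!r}")
    return v


@dataclass(frozen=True)
class CalibrationSpec:
    """Parameters mapping pixel distances to physical lengths.

    Use the :meth:`from_ppi`, :meth:`from_display` or
    :meth:`from_known_distance` constructors rather than filling fields by
    hand.
    """

    mode: str  # "ppi" | "known-distance"
    ppi: Optional[float] = None
    known_px: Optional[float] = None
    known_mm: Optional[float] = None
    image_resolution: Optional[Tuple[int, int]] = None
    screen_resolution: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.mode == "ppi":
            if self.ppi is None:
                raise InvalidCalibrationError("ppi mode requires a ppi value")
            _positive(self.ppi, "ppi")
        elif self.mode == "known-distance":
            if self.known_px is None or self.known_mm is None:
                raise InvalidCalibrationError(
                    "known-distance mode requires known_px and known_mm"
                )
            _positive(self.known_px, "known_px")
            _positive(self.known_mm, "known_mm")
        else:
            raise InvalidCalibrationError(f"unknown calibration mode {self.mode!r}")

    @classmethod
    def from_ppi(cls, ppi: float) -> "CalibrationSpec":
        return cls(mode="ppi", ppi=float(ppi))

    @classmethod
    def from_known_distance(cls, known_px: float, known_mm: float) -> "CalibrationSpec":
        return cls(mode="known-distance", known_px=float(known_px), known_mm=float(known_mm))

    @classmethod
    def from_display(cls, image_resolution: float, screen_resolution: float,
                     image_size: Optional[Tuple[int, int]] = None,
                     screen_size: Optional[Tuple[int, int]] = None) -> "CalibrationSpec":
        """Build a ppi-mode spec from the image/screen pixel-count ratio."""
        return cls(
            mode="ppi",
            ppi=compute_ppi(image_resolution, screen_resolution),
            image_resolution=image_size,
            screen_resolution=screen_size,
        )

    @property
    def mm_per_px(self) -> float:
        """Physical length of one pixel, in millimetres."""
        if self.mode == "ppi":
            return MM_PER_INCH / self.ppi
        return self.known_mm / self.known_px

    def describe(self) -> str:
        if self.mode == "ppi":
            return f"pixel density {self.ppi:g} PPI ({self.mm_per_px:g} mm/px)"
        return (
            f"known distance {self.known_px:g} px = {self.known_mm:g} mm "
            f"({self.mm_per_px:g} mm/px)"
        )


def compute_ppi(image_resolution: float, screen_resolution: float) -> float:
    """Effective pixel density from corresponding linear pixel counts.

    The ratio ``image_resolution / screen_resolution`` of matching linear
    dimensions (width over width) gives the display scale factor used as
    the divisor when converting on-screen pixel distances to inches.
    """
    return _positive(image_resolution, "image resolution") / _positive(
        screen_resolution, "screen resolution"
    )


def px_to_inch(d_px: float, ppi: float) -> float:
    """Convert a pixel distance to inches: d_px / ppi."""
    return float(d_px) / _positive(ppi, "ppi")


def px_to_mm(d_px: float, spec: CalibrationSpec) -> float:
    """Convert a pixel distance to millimetres under the given calibration."""
    if spec.mode == "ppi":
        return px_to_inch(d_px, spec.ppi) * MM_PER_INCH
    return float(d_px) * spec.known_mm / spec.known_px


def mm_to_px(d_mm: float, spec: CalibrationSpec) -> float:
    """Inverse of :func:`px_to_mm`."""
    return float(d_mm) / spec.mm_per_px
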