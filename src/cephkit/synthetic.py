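"""Synthetic cephalometric studies with known ground truth.

Real lateral cephalograms and their manual tracings are patient data and
cannot ship with the package, so every downstream module is exercised on
synthetic material instead: a frozen, anatomically plausible 11-landmark
template on a 1024 x 1024 canvas, per-case isotropic Gaussian landmark
placement noise, and a simulated "manual" measurement arm that adds
Gaussian noise (and optionally a per-parameter bias) to the true values.

The template was constructed once, by rotating rays to standard adult
angular values (SNA 90.7, SNB 86.6, ANB 4.1, FMA 33.9, PP-MP 33.3,
saddle angle 112.8 degrees), and is frozen here; at the default 0.2 mm/px
calibration its S-N length is ~70 mm, a realistic adult value.

Default study conditions: 30 cases, landmark placement noise 1.5 px,
manual noise 0.5 mm on distances and 1.0 degree on angles, no bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional

import numpy as np
from scipy import ndimage

from .calibration import CalibrationSpec
from .errors import InvalidInputError, MissingLandmarkError
from .evaluation import PairedMeasurementTable
from .geometry import Point2D
from .model import (
    ALL_DEFINITIONS,
    LANDMARKS,
    LINEAR_DEFINITIONS,
    LandmarkSet,
    MeasurementResult,
    measure_all,
)

__all__ = [
    "CANVAS_SIZE",
    "TEMPLATE_POINTS",
    "DEFAULT_CALIBRATION",
    "TemplateConfig",
    "SyntheticCase",
    "default_template",
    "template_landmark_set",
    "generate_cases",
    "generate_paired_study",
    "render_radiograph",
]

CANVAS_SIZE = (1024, 1024)

#: Frozen template landmark coordinates (image pixels, origin top-left).
TEMPLATE_POINTS: Dict[str, Point2D] = {
    "S": Point2D(400.0, 384.0),
    "N": Point2D(745.0, 334.0),
    "A": Point2D(796.3, 660.0),
    "B": Point2D(784.7, 802.3),
    "Ar": Point2D(352.3, 567.9),
    "Po": Point2D(330.0, 504.0),
    "Or": Point2D(700.0, 496.0),
    "Me": Point2D(690.0, 864.0),
    "Go": Point2D(336.4, 637.3),
    "ANS": Point2D(790.0, 594.0),
    "PNS": Point2D(510.0, 597.1),
}

#: Study calibration: 127 PPI, i.e. 0.2 mm per pixel.
DEFAULT_CALIBRATION = CalibrationSpec.from_ppi(127.0)


@dataclass(frozen=True)
class TemplateConfig:
    """Parameters of a simulated multi-case measurement study."""

    template_points: Mapping[str, Point2D] = field(
        default_factory=lambda: dict(TEMPLATE_POINTS)
    )
    landmark_sigma: float = 1.5  # px, isotropic placement noise per landmark
    manual_linear_sigma: float = 0.5  # mm, manual-arm noise on distances
    manual_angular_sigma: float = 1.0  # deg, manual-arm noise on angles
    manual_bias: Mapping[str, float] = field(default_factory=dict)  # per parameter
    n_cases: int = 30
    seed: int = 42

    def __post_init__(self) -> None:
        missing = [c for c in LANDMARKS if c not in self.template_points]
        if missing:
            raise InvalidInputError(f"template missing landmark(s): {missing}")
        for name, value in (
            ("landmark_sigma", self.landmark_sigma),
            ("manual_linear_sigma", self.manual_linear_sigma),
            ("manual_angular_sigma", self.manual_angular_sigma),
        ):
            if not np.isfinite(value) or value < 0:
                raise InvalidInputError(f"{name} must be >= 0, got {value!r}")
        if self.n_cases < 1:
            raise InvalidInputError(f"n_cases must be >= 1, got {self.n_cases}")
        unknown = [p for p in self.manual_bias if p not in {d.name for d in ALL_DEFINITIONS}]
        if unknown:
            raise InvalidInputError(f"manual_bias names unknown parameter(s): {unknown}")

    def with_(self, **changes) -> "TemplateConfig":
        return replace(self, **changes)


@dataclass
class SyntheticCase:
    """One simulated case: landmarks, their true measurements, and a noisy manual arm."""

    landmarks: LandmarkSet
    truth: List[MeasurementResult]
    manual: List[MeasurementResult]


def default_template() -> TemplateConfig:
    """The frozen template under default study conditions."""
    return TemplateConfig()


def template_landmark_set(cfg: Optional[TemplateConfig] = None,
                          case_id: str = "template") -> LandmarkSet:
    """The template itself as a measurable landmark set (no noise)."""
    cfg = cfg or default_template()
    return LandmarkSet(
        points=dict(cfg.template_points), case_id=case_id, image_size=CANVAS_SIZE
    )


def generate_cases(cfg: TemplateConfig,
                   cal: CalibrationSpec = DEFAULT_CALIBRATION) -> List[SyntheticCase]:
    """Simulate ``cfg.n_cases`` cases, fully determined by ``cfg.seed``.

    Each landmark is the template position plus an isotropic Gaussian
    offset of SD ``landmark_sigma``; the stored truth is ``measure_all``
    on those perturbed landmarks, and the manual arm adds Gaussian noise
    (linear sigma in mm, angular in degrees) plus any configured bias.
    """
    rng = np.random.default_rng(cfg.seed)
    linear_names = {d.name for d in LINEAR_DEFINITIONS}
    cases: List[SyntheticCase] = []
    for i in range(cfg.n_cases):
        points = {
            code: Point2D(
                p.x + rng.normal(0.0, cfg.landmark_sigma),
                p.y + rng.normal(0.0, cfg.landmark_sigma),
            )
            for code, p in cfg.template_points.items()
        }
        ls = LandmarkSet(points=points, case_id=f"case{i + 1:03d}", image_size=CANVAS_SIZE)
        truth = measure_all(ls, cal)
        manual = []
        for m in truth:
            sigma = (
                cfg.manual_linear_sigma if m.name in linear_names
                else cfg.manual_angular_sigma
            )
            value = m.value + rng.normal(0.0, sigma) + cfg.manual_bias.get(m.name, 0.0)
            manual.append(MeasurementResult(m.name, m.kind, value, m.unit))
        cases.append(SyntheticCase(landmarks=ls, truth=truth, manual=manual))
    return cases


def generate_paired_study(cfg: TemplateConfig,
                          cal: CalibrationSpec = DEFAULT_CALIBRATION) -> PairedMeasurementTable:
    """A ready-to-analyse paired table: auto = truth, manual = truth + noise + bias."""
    cases = generate_cases(cfg, cal)
    names = [d.name for d in ALL_DEFINITIONS]
    kinds = [d.kind for d in ALL_DEFINITIONS]
    units = ["mm" if k == "linear" else "deg" for k in kinds]
    auto = np.array([[c.truth[i].value for c in cases] for i in range(len(names))])
    manual = np.array([[c.manual[i].value for c in cases] for i in range(len(names))])
    return PairedMeasurementTable.from_arrays(
        parameters=names,
        cases=[c.landmarks.case_id for c in cases],
        auto=auto,
        manual=manual,
        kinds=kinds,
        units=units,
    )


def render_radiograph(ls: LandmarkSet, noise_sigma: float = 0.03,
                      seed: int = 0) -> np.ndarray:
    """Render a radiograph-like 1024 x 1024 test image from a landmark set.

    Not an anatomical simulation: a smooth intensity ramp, blurred bright
    ridges along the 12 measured segments, bright blobs at the landmarks,
    and additive Gaussian noise — enough structure to exercise the
    enhancement filters deterministically.
    """
    if not ls.complete:
        raise MissingLandmarkError(ls.missing())
    if not np.isfinite(noise_sigma) or noise_sigma < 0:
        raise InvalidInputError(f"noise_sigma must be >= 0, got {noise_sigma!r}")
    w, h = CANVAS_SIZE
    yy, xx = np.mgrid[0:h, 0:w]
    # smooth diagonal illumination ramp, 0.15 .. 0.45
    img = 0.15 + 0.30 * (xx + yy) / (w + h - 2)

    structure = np.zeros((h, w))
    from skimage.draw import line as _line  # local import keeps module load light

    for d in LINEAR_DEFINITIONS:
        a, b = (ls.points[c] for c in d.operands)
        rr, cc = _line(int(round(a.y)), int(round(a.x)), int(round(b.y)), int(round(b.x)))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        structure[rr[keep], cc[keep]] = 1.0
    structure = ndimage.gaussian_filter(structure, sigma=1.5)
    img = img + 0.25 * structure / max(structure.max(), 1e-12)

    for p in ls.points.values():
        r2 = (xx - p.x) ** 2 + (yy - p.y) ** 2
        img = img + 0.40 * np.exp(-r2 / (2.0 * 4.0**2))

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)
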