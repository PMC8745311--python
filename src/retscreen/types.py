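"""Shared domain types for the imaging pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Lesion type codes: dark ("red") lesions MA/HEM, bright ("white") EX/CWS.
LESION_TYPES = ("MA", "HEM", "EX", "CWS")
DARK_TYPES = ("MA", "HEM")
BRIGHT_TYPES = ("EX", "CWS")

EYES = ("OD", "OS")


@dataclass
class FundusImage:
    """One fundus capture: an 8-bit RGB raster plus its identity.

    Pixel coordinates are 0-based with ``x`` the column and ``y`` the row.
    """

    pixels: np.ndarray  # H x W x 3, uint8
    patient_id: str = ""
    eye: str = "OD"
    capture_index: int = 1
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty H x W x 3 raster")
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        self.pixels = px

    @property
    def green(self) -> np.ndarray:
        """The green plane, the channel with the best lesion/vessel contrast."""
        return self.pixels[:, :, 1]


@dataclass
class QualityReport:
    """Gradability decision with the metrics that produced it.

    ``sharpness`` is the mean gradient-energy of the green plane inside the
    field (unitless); ``illuminated_fraction`` and ``saturation_fraction`` are
    fractions of field pixels above the exposure floor / at sensor maximum.
    """

    gradable: bool
    sharpness: float
    illuminated_fraction: float
    saturation_fraction: float
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for frac in (self.illuminated_fraction, self.saturation_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class VesselMap:
    """Binary vessel mask and its morphological skeleton (skeleton ⊆ mask)."""

    mask: np.ndarray
    skeleton: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.shape != self.skeleton.shape:
            raise ValueError("mask and skeleton must share a shape")
        if np.any(self.skeleton & ~self.mask):
            raise ValueError("skeleton must be a subset of the mask")


@dataclass
class RetinalCoordinateFrame:
    """Fovea-centred topographic frame in disc-diameter (dd) units.

    ``axis_angle`` is the direction (degrees, image convention: x right,
    y down) of the fovea→disc vector; lesion polar angles are measured from
    this axis, positive toward the superior retina.
    """

    disc_center: tuple[float, float]
    disc_radius: float
    fovea_center: tuple[float, float]
    axis_angle: float

    def __post_init__(self) -> None:
        if self.disc_radius <= 0:
            raise ValueError("disc_radius must be positive")
        if tuple(self.disc_center) == tuple(self.fovea_center):
            raise ValueError("disc and fovea centers must differ")

    @property
    def dd(self) -> float:
        """One disc diameter in pixels, the retinal distance unit."""
        return 2.0 * self.disc_radius

    def to_polar(self, x: float, y: float) -> tuple[float, float]:
        """Map a pixel position to (r in dd from fovea, θ degrees from axis).

        θ is positive toward the superior retina (up in the image, i.e.
        decreasing y), so a horizontal mirror flips its sign.
        """
        fx, fy = self.fovea_center
        dx, dy = x - fx, y - fy
        r = float(np.hypot(dx, dy)) / self.dd
        ang = np.degrees(np.arctan2(dy, dx)) - self.axis_angle
        # image y grows downward; negate so positive θ is superior
        theta = -((ang + 180.0) % 360.0 - 180.0)
        return r, float(theta)

    def quadrant_of(self, theta: float) -> int:
        """Quadrant 1..4: the four 90° sectors centred on/around the axis."""
        t = (theta + 360.0) % 360.0
        return int(t // 90.0) + 1


@dataclass
class LesionCandidate:
    """A detected lesion with geometry, structural features and polar position."""

    type: str  # MA | HEM | EX | CWS
    centroid: tuple[float, float]  # (x, y) px
    area: float  # px^2
    circularity: float  # 4*pi*A / P^2
    contrast: float  # mean intensity difference vs local background
    polar: Optional[tuple[float, float]] = None  # (r in dd, theta deg)
    quadrant: Optional[int] = None

    def __post_init__(self) -> None:
        if self.type not in LESION_TYPES:
            raise ValueError(f"unknown lesion type {self.type!r}")
        if self.area <= 0:
            raise ValueError("area must be positive")


@dataclass
class ImageAnalysis:
    """Full per-image analysis result.

    Lesions may be non-empty even when the image is not gradable: a lesion
    finding overrides quality at grading time.
    """

    quality: QualityReport
    frame: Optional[RetinalCoordinateFrame] = None
    vessels: Optional[VesselMap] = None
    lesions: list[LesionCandidate] = field(default_factory=list)
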