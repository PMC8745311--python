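"""Classical fundus image analysis: quality gating, vessels, landmarks, lesions.

All stages operate on the green channel, which carries the best contrast for
both the vascular tree and retinal lesions, restricted to the circular camera
field. The pipeline is deterministic — a pure function of the pixels and the
threshold configuration — and degrades gracefully: an ungradable image is
still searched for lesions, because a lesion finding overrides image quality
at grading time.

Stage order and operators:

1. quality gating on sharpness (gradient energy), illumination and saturation;
2. vessel extraction by multi-orientation morphological black top-hat on the
   green plane, with elongation filtering to reject compact dark blobs;
3. optic-disc localization from a binary mask of the brightest green pixels,
   macula localization as the darkest smoothed region in a 2–3 disc-diameter
   annulus near the disc's horizontal axis; these define a fovea-centred
   polar coordinate frame in disc-diameter (dd) units;
4. dark-lesion detection (microaneurysm/hemorrhage) from the dark residual
   objects left after suppressing vessel pixels, with structural filtering on
   area, contrast and circularity;
5. bright-lesion detection (exudate/cotton-wool spot) by white top-hat,
   excluding the disc, classified by boundary edge sharpness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from retscreen.types import (
    FundusImage,
    ImageAnalysis,
    LesionCandidate,
    QualityReport,
    RetinalCoordinateFrame,
    VesselMap,
)


class LandmarkNotFoundError(RuntimeError):
    """Raised when the disc or macula cannot be located."""


@dataclass
class QualityThresholds:
    """Gradability bounds (calibrated once on the generator's degradation sweep).

    ``sharpness_min`` sits in the gap between the shading-corrected gradient
    energy just at the documented blur failure level (sigma 4 -> 4.19-4.80
    over seeds) and just beyond it (sigma 4.5 -> 3.54-4.01), so the flag flips
    exactly where the generator documents gradability to end. The score is
    computed on a shading-corrected plane, so exposure level and vignetting
    within their documented limits do not move it.
    """

    sharpness_min: float = 4.10
    illumination_floor: float = 35.0  # 8-bit green level counted as exposed
    illuminated_fraction_min: float = 0.60
    saturation_fraction_max: float = 0.20
    min_image_size: int = 64
    field_floor: float = 12.0  # mean-RGB level separating field from surround


@dataclass
class VesselParams:
    """Black top-hat vessel extraction parameters."""

    line_length: int = 19  # px; longer than any lesion diameter
    n_orientations: int = 8  # mirror-symmetric angle set
    contrast_min: float = 10.0  # top-hat response threshold (8-bit units)
    min_object_area: int = 60  # px^2
    min_elongation: float = 2.5  # major/minor axis ratio to count as vessel
    large_component_area: int = 1500  # px^2; a connected tree passes regardless


@dataclass
class DarkLesionParams:
    """Structural-characteristic thresholds for dark residual objects."""

    tophat_radius: int = 14  # px; covers the largest expected hemorrhage
    contrast_min: float = 12.0  # mean residual over the object (8-bit units)
    area_min: float = 6.0
    area_max: float = 1500.0
    area_ma_max: float = 60.0  # px^2; above this a candidate is HEM
    circularity_ma_min: float = 0.70
    vessel_dilation: int = 2  # px of slack around the vessel mask
    fovea_exclusion_dd: float = 0.30  # keep clear of the foveal dip


@dataclass
class BrightLesionParams:
    """White top-hat bright-lesion parameters."""

    tophat_radius: int = 14
    contrast_min: float = 30.0
    area_min: float = 12.0
    area_max: float = 2500.0
    circularity_min: float = 0.45  # rejects elongated vessel-adjacent artifacts
    disc_margin_dd: float = 0.10  # exclusion ring added to the disc circle
    field_erosion: int = 6  # px; keeps the field-rim gradient out
    edge_sharpness_min: float = 200.0  # boundary Sobel: EX above, CWS below


@dataclass
class LandmarkParams:
    disc_quantile: float = 0.99  # brightest fraction of field pixels
    disc_radius_min_frac: float = 1.0 / 40.0  # of image width
    disc_radius_max_frac: float = 1.0 / 8.0
    fovea_annulus_dd: tuple[float, float] = (2.0, 3.0)
    fovea_axis_halfangle: float = 30.0  # degrees about the horizontal
    fovea_smooth_dd: float = 0.25


@dataclass
class PipelineConfig:
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    vessels: VesselParams = field(default_factory=VesselParams)
    dark: DarkLesionParams = field(default_factory=DarkLesionParams)
    bright: BrightLesionParams = field(default_factory=BrightLesionParams)
    landmarks: LandmarkParams = field(default_factory=LandmarkParams)


DEFAULT_CONFIG = PipelineConfig()


# ---------------------------------------------------------------------------
# field detection and quality


def detect_field_mask(image: FundusImage, floor: float = 12.0) -> np.ndarray:
    """Binary mask of the circular camera field (pixels above the dark surround)."""
    mean = image.pixels.astype(float).mean(axis=2)
    mask = mean > floor
    if not mask.any():
        return mask
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum(mask, labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def assess_quality(
    image: FundusImage, thresholds: Optional[QualityThresholds] = None
) -> QualityReport:
    """Deterministic gradability check inside the detected field circle."""
    t = thresholds or QualityThresholds()
    h, w = image.pixels.shape[:2]
    if h < t.min_image_size or w < t.min_image_size:
        raise ValueError(f"image {w}x{h} below minimum size {t.min_image_size}")

    fieldm = detect_field_mask(image, t.field_floor)
    if fieldm.sum() < 0.05 * h * w:
        return QualityReport(
            gradable=False,
            sharpness=0.0,
            illuminated_fraction=0.0,
            saturation_fraction=0.0,
            reasons=["underexposed"],
        )
    # erode well past any plausible blur spread so the field boundary's own
    # (possibly smeared) edge does not count as sharpness
    inner = ndimage.binary_erosion(fieldm, iterations=30)
    g = image.green.astype(float) / 255.0
    # shading-correct before measuring: divide by a heavily smoothed background
    # (normalized convolution confined to the field) so exposure level and
    # vignetting cancel and only local structure remains
    sigma_bg = max(h, w) / 16.0
    m = fieldm.astype(float)
    background = ndimage.gaussian_filter(g * m, sigma_bg)
    weight = ndimage.gaussian_filter(m, sigma_bg)
    corrected = np.where(fieldm, g / np.maximum(background / np.maximum(weight, 1e-9), 1e-3), 1.0)
    gx = ndimage.sobel(corrected, axis=1)
    gy = ndimage.sobel(corrected, axis=0)
    sharpness = float(np.mean((gx**2 + gy**2)[inner]) * 1e3)
    green = image.green.astype(float)
    illuminated = float(np.mean(green[fieldm] > t.illumination_floor))
    saturated = float(np.mean(green[fieldm] >= 255))

    reasons = []
    if sharpness < t.sharpness_min:
        reasons.append("blur")
    if illuminated < t.illuminated_fraction_min:
        reasons.append("underexposed")
    if saturated > t.saturation_fraction_max:
        reasons.append("overexposed")
    return QualityReport(
        gradable=not reasons,
        sharpness=sharpness,
        illuminated_fraction=illuminated,
        saturation_fraction=saturated,
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# vessels


def _line_footprint(length: int, angle_deg: float) -> np.ndarray:
    """Boolean line structuring element of the given length and orientation."""
    half = (length - 1) / 2.0
    t = np.linspace(-half, half, 2 * length)
    xs = np.round(t * math.cos(math.radians(angle_deg))).astype(int)
    ys = np.round(t * math.sin(math.radians(angle_deg))).astype(int)
    xs -= xs.min()
    ys -= ys.min()
    fp = np.zeros((ys.max() + 1, xs.max() + 1), dtype=bool)
    fp[ys, xs] = True
    return fp


def segment_vessels(
    green: np.ndarray, field_mask: np.ndarray, params: Optional[VesselParams] = None
) -> VesselMap:
    """Extract the dark vascular tree from the green plane.

    Multi-orientation black top-hat (maximum response over a mirror-symmetric
    set of line orientations) enhances dark elongated structures; a global
    contrast threshold, size filter and elongation filter then reject noise
    and compact dark blobs (lesions). The skeleton is the morphological
    medial axis of the mask.
    """
    p = params or VesselParams()
    if not np.any(field_mask):
        raise ValueError("empty field mask")
    g = ndimage.gaussian_filter(green.astype(float), 1.0)
    enhanced = np.zeros_like(g)
    angles = np.arange(p.n_orientations) * (180.0 / p.n_orientations)
    for ang in angles:
        fp = _line_footprint(p.line_length, ang)
        closed = ndimage.grey_closing(g, footprint=fp)
        np.maximum(enhanced, closed - g, out=enhanced)
    inner = ndimage.binary_erosion(field_mask, iterations=3)
    enhanced[~inner] = 0.0

    mask = enhanced > p.contrast_min
    mask = morphology.remove_small_objects(mask, max_size=p.min_object_area)
    labels = measure.label(mask)
    keep = np.zeros_like(mask)
    for region in measure.regionprops(labels):
        if region.area >= p.large_component_area:
            keep[labels == region.label] = True
            continue
        minor = max(region.axis_minor_length, 1e-6)
        if region.axis_major_length / minor >= p.min_elongation:
            keep[labels == region.label] = True
    skeleton = morphology.skeletonize(keep)
    return VesselMap(mask=keep, skeleton=skeleton & keep)


# ---------------------------------------------------------------------------
# landmarks


def locate_landmarks(
    green: np.ndarray,
    field_mask: np.ndarray,
    params: Optional[LandmarkParams] = None,
) -> RetinalCoordinateFrame:
    """Locate the optic disc and macula; build the topographic frame.

    The disc is the largest plausible-size component of a binary mask of the
    brightest green pixels (ties broken by size then brightness); the fovea is
    the minimum of the smoothed green plane in a 2–3 dd annulus within ±30° of
    the disc's horizontal axis, searched on the temporal side.
    """
    p = params or LandmarkParams()
    if not np.any(field_mask):
        raise LandmarkNotFoundError("disc not found: empty field")
    h, w = green.shape
    g = ndimage.gaussian_filter(green.astype(float), 2.0)
    thresh = np.quantile(g[field_mask], p.disc_quantile)
    # close + fill so vessels crossing the disc do not split the component
    binmask = ndimage.binary_fill_holes(
        morphology.closing((g >= thresh) & field_mask, morphology.disk(5))
    )
    labels = measure.label(binmask)
    r_min = p.disc_radius_min_frac * w
    r_max = p.disc_radius_max_frac * w
    best = None
    for region in measure.regionprops(labels, intensity_image=g):
        r_eq = math.sqrt(region.area / math.pi)
        if not r_min <= r_eq <= r_max:
            continue
        key = (region.area, region.intensity_mean)
        if best is None or key > best[0]:
            best = (key, region)
    if best is None:
        raise LandmarkNotFoundError("disc not found")
    region = best[1]
    cy, cx = region.centroid

    # refine: re-threshold locally at the midpoint between the field's median
    # and the disc peak, which recovers the full disc plateau
    peak = float(region.intensity_max)
    background = float(np.median(g[field_mask]))
    local = np.zeros_like(binmask)
    r_window = int(3 * math.sqrt(region.area / math.pi)) + 5
    y0, y1 = max(int(cy) - r_window, 0), min(int(cy) + r_window + 1, h)
    x0, x1 = max(int(cx) - r_window, 0), min(int(cx) + r_window + 1, w)
    local[y0:y1, x0:x1] = g[y0:y1, x0:x1] >= (background + 0.55 * (peak - background))
    local &= field_mask
    local = ndimage.binary_fill_holes(
        morphology.closing(local, morphology.disk(5))
    )
    lab2 = measure.label(local)
    lab_at = lab2[int(round(cy)), int(round(cx))]
    if lab_at > 0:
        refined = measure.regionprops((lab2 == lab_at).astype(int))[0]
        r_eq = math.sqrt(refined.area / math.pi)
        if r_min <= r_eq <= r_max:
            cy, cx = refined.centroid
            region = refined
    disc_radius = math.sqrt(region.area / math.pi)
    disc_center = (cx, cy)
    dd = 2.0 * disc_radius

    # fovea search: temporal side = toward the field centre
    fy_smooth = ndimage.gaussian_filter(green.astype(float), p.fovea_smooth_dd * dd)
    yy, xx = np.mgrid[0:h, 0:w]
    field_cx = np.mean(xx[field_mask])
    direction = -1.0 if cx >= field_cx else 1.0  # temporal x-direction
    dxp = (xx - cx) * direction
    dyp = yy - cy
    dist = np.hypot(dxp, dyp)
    ang = np.degrees(np.arctan2(np.abs(dyp), dxp))  # 0 along temporal horizontal
    lo, hi = p.fovea_annulus_dd
    search = (
        field_mask
        & (dist >= lo * dd)
        & (dist <= hi * dd)
        & (ang <= p.fovea_axis_halfangle)
    )
    if not np.any(search):
        raise LandmarkNotFoundError("macula not found: empty search region")
    masked = np.where(search, fy_smooth, np.inf)
    fy_idx = np.unravel_index(np.argmin(masked), masked.shape)
    fovea_center = (float(fy_idx[1]), float(fy_idx[0]))

    axis_angle = math.degrees(
        math.atan2(cy - fovea_center[1], cx - fovea_center[0])
    )
    return RetinalCoordinateFrame(
        disc_center=disc_center,
        disc_radius=disc_radius,
        fovea_center=fovea_center,
        axis_angle=axis_angle,
    )


# ---------------------------------------------------------------------------
# lesions


def _candidate_from_region(
    region, residual: np.ndarray, frame: Optional[RetinalCoordinateFrame]
) -> dict:
    cy, cx = region.centroid
    perimeter = max(region.perimeter, 1e-6)
    circularity = min(4.0 * math.pi * region.area / perimeter**2, 1.05)
    contrast = float(region.intensity_mean)
    polar = quadrant = None
    if frame is not None:
        r, theta = frame.to_polar(cx, cy)
        polar = (r, theta)
        quadrant = frame.quadrant_of(theta)
    return dict(
        centroid=(cx, cy),
        area=float(region.area),
        circularity=circularity,
        contrast=contrast,
        polar=polar,
        quadrant=quadrant,
    )


def detect_dark_lesions(
    green: np.ndarray,
    vessels: VesselMap,
    frame: RetinalCoordinateFrame,
    field_mask: np.ndarray,
    params: Optional[DarkLesionParams] = None,
) -> list[LesionCandidate]:
    """Microaneurysm/hemorrhage candidates from dark residual objects.

    Dark blobs are what remains of the black top-hat after suppressing the
    vessel mask; structural filtering keeps objects by area and contrast, and
    small near-circular objects are microaneurysms, the rest hemorrhages.
    """
    p = params or DarkLesionParams()
    g = green.astype(float)
    residual = ndimage.grey_closing(g, footprint=morphology.disk(p.tophat_radius)) - g
    suppress = ndimage.binary_dilation(vessels.mask, iterations=p.vessel_dilation)
    residual[suppress] = 0.0
    inner = ndimage.binary_erosion(field_mask, iterations=3)
    residual[~inner] = 0.0
    # exclude the disc: vessels converge there and shadows masquerade as blobs
    yy, xx = np.mgrid[0 : g.shape[0], 0 : g.shape[1]]
    dxc, dyc = frame.disc_center
    residual[np.hypot(xx - dxc, yy - dyc) < frame.disc_radius + 0.1 * frame.dd] = 0.0

    mask = residual > 0.5 * p.contrast_min
    labels = measure.label(mask)
    out: list[LesionCandidate] = []
    for region in measure.regionprops(labels, intensity_image=residual):
        if not p.area_min <= region.area <= p.area_max:
            continue
        feats = _candidate_from_region(region, residual, frame)
        if feats["contrast"] < p.contrast_min:
            continue
        if feats["polar"] is not None and feats["polar"][0] < p.fovea_exclusion_dd:
            continue
        ltype = (
            "MA"
            if region.area <= p.area_ma_max
            and feats["circularity"] >= p.circularity_ma_min
            else "HEM"
        )
        out.append(LesionCandidate(type=ltype, **feats))
    return out


def detect_bright_lesions(
    green: np.ndarray,
    frame: RetinalCoordinateFrame,
    field_mask: np.ndarray,
    params: Optional[BrightLesionParams] = None,
) -> list[LesionCandidate]:
    """Exudate/cotton-wool candidates from the white top-hat of the green plane.

    Components overlapping the (slightly dilated) disc circle are excluded;
    sharp-edged objects are exudates, soft-edged ones cotton-wool spots.
    """
    p = params or BrightLesionParams()
    g = green.astype(float)
    residual = g - ndimage.grey_opening(g, footprint=morphology.disk(p.tophat_radius))
    inner = ndimage.binary_erosion(field_mask, iterations=p.field_erosion)
    residual[~inner] = 0.0

    yy, xx = np.mgrid[0 : g.shape[0], 0 : g.shape[1]]
    dxc, dyc = frame.disc_center
    disc_zone = (
        np.hypot(xx - dxc, yy - dyc)
        < frame.disc_radius + p.disc_margin_dd * frame.dd
    )

    gx = ndimage.sobel(g, axis=1)
    gy = ndimage.sobel(g, axis=0)
    grad = np.hypot(gx, gy)

    mask = residual > 0.5 * p.contrast_min
    labels = measure.label(mask)
    out: list[LesionCandidate] = []
    for region in measure.regionprops(labels, intensity_image=residual):
        if not p.area_min <= region.area <= p.area_max:
            continue
        coords = region.coords
        if disc_zone[coords[:, 0], coords[:, 1]].any():
            continue
        feats = _candidate_from_region(region, residual, frame)
        if feats["contrast"] < p.contrast_min:
            continue
        if feats["circularity"] < p.circularity_min:
            continue
        # boundary pixels: object minus its erosion
        obj = labels == region.label
        boundary = obj & ~ndimage.binary_erosion(obj)
        edge_sharpness = float(np.mean(grad[boundary]))
        ltype = "EX" if edge_sharpness >= p.edge_sharpness_min else "CWS"
        out.append(LesionCandidate(type=ltype, **feats))
    return out


# ---------------------------------------------------------------------------
# orchestration


def analyze_image(
    image: FundusImage, config: Optional[PipelineConfig] = None
) -> ImageAnalysis:
    """Run the full pipeline on one capture.

    Quality is assessed first but does not gate detection: lesions found on an
    ungradable image still count at grading time. Landmark failures are
    recorded as reasons rather than raised.
    """
    cfg = config or DEFAULT_CONFIG
    quality = assess_quality(image, cfg.quality)
    fieldm = detect_field_mask(image, cfg.quality.field_floor)
    frame = None
    vessels = None
    lesions: list[LesionCandidate] = []
    if np.any(fieldm):
        try:
            vessels = segment_vessels(image.green, fieldm, cfg.vessels)
            frame = locate_landmarks(image.green, fieldm, cfg.landmarks)
            lesions = detect_dark_lesions(
                image.green, vessels, frame, fieldm, cfg.dark
            ) + detect_bright_lesions(image.green, frame, fieldm, cfg.bright)
        except LandmarkNotFoundError as exc:
            quality.reasons.append(str(exc))
    return ImageAnalysis(quality=quality, frame=frame, vessels=vessels, lesions=lesions)


def render_overlay(image: FundusImage, analysis: ImageAnalysis) -> np.ndarray:
    """Overlay raster: red lesions in red, white lesions in blue, polar grid.

    The grid is centred on the fovea with rings at 1 and 2 dd and radial
    spokes at the quadrant boundaries.
    """
    from skimage import draw

    if analysis.frame is None:
        raise ValueError("analysis has no coordinate frame; cannot render overlay")
    frame = analysis.frame
    out = image.pixels.copy()
    h, w = out.shape[:2]
    grid_color = (255, 255, 0)
    fx, fy = frame.fovea_center
    for ring_dd in (1.0, 2.0):
        rr, cc = draw.circle_perimeter(
            int(round(fy)), int(round(fx)), int(round(ring_dd * frame.dd)), shape=(h, w)
        )
        out[rr, cc] = grid_color
    for k in range(4):
        ang = math.radians(frame.axis_angle + 90.0 * k)
        ex = fx + 2.0 * frame.dd * math.cos(ang)
        ey = fy + 2.0 * frame.dd * math.sin(ang)
        rr, cc, _ = draw.line_aa(
            int(round(fy)),
            int(round(fx)),
            int(np.clip(round(ey), 0, h - 1)),
            int(np.clip(round(ex), 0, w - 1)),
        )
        out[rr, cc] = grid_color
    for cand in analysis.lesions:
        color = (255, 0, 0) if cand.type in ("MA", "HEM") else (0, 0, 255)
        radius = max(int(round(math.sqrt(cand.area / math.pi))) + 4, 6)
        cx, cy = cand.centroid
        for r_px in (radius, radius + 1):
            rr, cc = draw.circle_perimeter(
                int(round(cy)), int(round(cx)), r_px, shape=(h, w)
            )
            out[rr, cc] = color
    return out
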