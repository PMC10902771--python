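"""The head-circumference measurement pipeline.

Given a photograph containing one head-like oval region and one circular
reference object of known physical diameter, the pipeline

1. segments the head as the largest oval foreground component
   (:func:`segment_head`),
2. fits an ellipse to its contour by direct least squares
   (:func:`fit_ellipse`),
3. pulls the fit toward four manually supplied landmark points — top,
   bottom and the two outermost lateral edges of the head
   (:func:`fuse_landmarks`),
4. recovers the pixels-per-cm scale from the reference object
   (:func:`detect_reference`), and
5. reports the circumference of the fused ellipse in cm via the
   Ramanujan-II perimeter (:func:`measure_hc`).

The circumference is taken from the fitted ellipse rather than the raw pixel
contour: digitized contours systematically overestimate arc length, while an
ellipse perimeter is stable under re-rasterization. The raw contour arc
length is still exposed as a diagnostic on the result.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure
from skimage import morphology
from skimage.color import rgb2hsv

from . import geometry
from .errors import (
    InvalidArgumentError,
    InvalidLandmarksError,
    NoHeadFoundError,
    NoReferenceFoundError,
)
from .geometry import EllipseParams

__all__ = [
    "Contour",
    "Landmarks",
    "ScaleCalibration",
    "ColorSpec",
    "HCMeasurement",
    "BLUE_REFERENCE",
    "segment_head",
    "detect_reference",
    "fit_ellipse",
    "fuse_landmarks",
    "ellipse_perimeter_cm",
    "contour_arc_length_px",
    "measure_hc",
]

# Ellipse-residual gate: a candidate's RMS fit residual must stay below this
# fraction of its equivalent radius to count as "oval".
OVAL_RESIDUAL_FRACTION = 0.05
# Reference detection: minimum circularity 4*pi*A/P^2.
MIN_REFERENCE_CIRCULARITY = 0.85
# Each manual landmark counts as this many contour points in the fused fit.
LANDMARK_WEIGHT = 100.0


@dataclass(frozen=True)
class Contour:
    """Closed boundary of a segmented region, subpixel (x, y) coordinates."""

    points: np.ndarray  # (n, 2), first point == last point adjacency implied
    area_px2: float

    def __post_init__(self):
        if len(self.points) < 5:
            raise InvalidArgumentError("a contour needs at least 5 points")


@dataclass(frozen=True)
class Landmarks:
    """Four manual points: top, bottom and the two outermost lateral edges.

    Image convention: y grows downward, so ``top.y < bottom.y``.
    """

    top: tuple
    bottom: tuple
    lateral_left: tuple
    lateral_right: tuple

    def __post_init__(self):
        pts = [tuple(map(float, p)) for p in
               (self.top, self.bottom, self.lateral_left, self.lateral_right)]
        object.__setattr__(self, "top", pts[0])
        object.__setattr__(self, "bottom", pts[1])
        object.__setattr__(self, "lateral_left", pts[2])
        object.__setattr__(self, "lateral_right", pts[3])
        if not self.top[1] < self.bottom[1]:
            raise InvalidLandmarksError("top landmark must lie above bottom landmark")
        if not self.lateral_left[0] < self.lateral_right[0]:
            raise InvalidLandmarksError("left landmark must lie left of right landmark")
        for i in range(4):
            for j in range(i + 1, 4):
                if pts[i] == pts[j]:
                    raise InvalidLandmarksError(f"landmarks coincide: {pts[i]}")

    def as_array(self) -> np.ndarray:
        return np.array([self.top, self.bottom, self.lateral_left, self.lateral_right])

    def transformed(self, fn) -> "Landmarks":
        """Apply ``fn((x, y)) -> (x, y)`` to each point (e.g. for rotations)."""
        moved = [tuple(fn(p)) for p in self.as_array()]
        ys = sorted(moved[:2], key=lambda p: p[1])
        xs = sorted(moved[2:], key=lambda p: p[0])
        return Landmarks(top=ys[0], bottom=ys[1], lateral_left=xs[0], lateral_right=xs[1])


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixels-per-cm conversion recovered from the reference object."""

    px_per_cm: float
    known_diameter_cm: float
    detected_diameter_px: float
    circularity: float


@dataclass(frozen=True)
class ColorSpec:
    """HSV window describing the reference object's color (all in [0, 1])."""

    hue_range: tuple = (0.50, 0.78)
    sat_min: float = 0.35
    val_min: float = 0.20


#: Default: a saturated blue disc (a bright bottle cap).
BLUE_REFERENCE = ColorSpec()


@dataclass
class HCMeasurement:
    """One head-circumference estimate.

    ``quality`` is the RMS residual (px) of the fused ellipse fit; it is the
    pipeline's internal figure of merit, small when the contour is truly
    elliptical. ``arc_length_cm`` is the raw pixel-contour arc length, kept
    as a diagnostic only.
    """

    hc_cm: float
    method: str = "app"
    quality: float = float("nan")
    ellipse: EllipseParams | None = None
    scale: ScaleCalibration | None = None
    arc_length_cm: float | None = None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "hc_cm": self.hc_cm,
            "method": self.method,
            "quality": self.quality,
            "warnings": list(self.warnings),
        }
        if self.ellipse is not None:
            e = self.ellipse
            d["ellipse"] = {
                "cx_px": e.cx_px, "cy_px": e.cy_px,
                "a_px": e.a_px, "b_px": e.b_px, "theta_rad": e.theta_rad,
            }
        if self.scale is not None:
            d["px_per_cm"] = self.scale.px_per_cm
            d["reference_circularity"] = self.scale.circularity
        if self.arc_length_cm is not None:
            d["arc_length_cm"] = self.arc_length_cm
        return d


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _foreground_mask(image: np.ndarray, threshold: float = 0.12) -> np.ndarray:
    """Foreground by color distance to the border-estimated background."""
    img = np.asarray(image, dtype=float) / 255.0
    border = np.concatenate([
        img[:3].reshape(-1, 3), img[-3:].reshape(-1, 3),
        img[:, :3].reshape(-1, 3), img[:, -3:].reshape(-1, 3),
    ])
    bg = np.median(border, axis=0)
    dist = np.sqrt(((img - bg) ** 2).sum(axis=-1))
    mask = dist > threshold
    return morphology.closing(mask, morphology.disk(3))


def _region_contour(region_mask: np.ndarray) -> np.ndarray | None:
    """Longest subpixel iso-contour of a binary region, as (x, y) points."""
    contours = skmeasure.find_contours(region_mask.astype(float), 0.5)
    if not contours:
        return None
    rc = max(contours, key=len)
    return rc[:, ::-1].copy()  # (row, col) -> (x, y)


def segment_head(image: np.ndarray) -> Contour:
    """Extract the closed outer contour of the best head-candidate region.

    Foreground components are gated on ovalness — the RMS ellipse-fit
    residual must not exceed ``OVAL_RESIDUAL_FRACTION`` of the component's
    equivalent radius — and the largest surviving component wins (ties by
    lower residual). Raises :class:`NoHeadFoundError` if nothing passes.
    """
    image = _as_rgb8(image)
    mask = _foreground_mask(image)
    labels = skmeasure.label(mask)
    candidates = []
    for region in skmeasure.regionprops(labels):
        if region.area < 200:
            continue
        rmask = labels == region.label
        pts = _region_contour(rmask)
        if pts is None or len(pts) < 5:
            continue
        try:
            ell = geometry.fit_ellipse_direct(pts)
        except Exception:
            continue
        resid = geometry.rms_residual(ell, pts)
        r_eq = np.sqrt(region.area / np.pi)
        if resid <= OVAL_RESIDUAL_FRACTION * r_eq:
            candidates.append((region.area, resid, pts))
    if not candidates:
        raise NoHeadFoundError("no foreground component passed the oval gate")
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, _, pts = candidates[0]
    area = _shoelace_area(pts)
    return Contour(points=pts, area_px2=area)


def _shoelace_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _as_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise InvalidArgumentError("expected an 8-bit RGB image (H, W, 3) uint8")
    return image


# ---------------------------------------------------------------------------
# reference detection / scale calibration
# ---------------------------------------------------------------------------

def detect_reference(image: np.ndarray, known_diameter_cm: float,
                     color_spec: ColorSpec = BLUE_REFERENCE) -> ScaleCalibration:
    """Recover the pixels-per-cm scale from the colored circular reference.

    Pixels inside the HSV window are masked; the connected component with
    the highest circularity ``4*pi*area/perimeter^2`` (must exceed 0.85) is
    taken as the reference, and its area-equivalent circle diameter divided
    by the known physical diameter gives ``px_per_cm``.
    """
    image = _as_rgb8(image)
    if known_diameter_cm <= 0:
        raise InvalidArgumentError(
            f"known_diameter_cm must be positive, got {known_diameter_cm}")
    hsv = rgb2hsv(image)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    lo, hi = color_spec.hue_range
    mask = (h >= lo) & (h <= hi) & (s >= color_spec.sat_min) & (v >= color_spec.val_min)
    mask = morphology.closing(mask, morphology.disk(2))
    labels = skmeasure.label(mask)
    best = None
    for region in skmeasure.regionprops(labels):
        if region.area < 50:
            continue
        per = region.perimeter_crofton
        if per <= 0:
            continue
        circ = min(1.0, 4.0 * np.pi * region.area / per**2)
        if circ > MIN_REFERENCE_CIRCULARITY and (best is None or circ > best[0]):
            best = (circ, region.equivalent_diameter_area)
    if best is None:
        raise NoReferenceFoundError(
            "no color-matched component with circularity > "
            f"{MIN_REFERENCE_CIRCULARITY}")
    circ, diam_px = best
    return ScaleCalibration(
        px_per_cm=float(diam_px) / known_diameter_cm,
        known_diameter_cm=float(known_diameter_cm),
        detected_diameter_px=float(diam_px),
        circularity=float(circ),
    )


# ---------------------------------------------------------------------------
# ellipse fitting and landmark fusion
# ---------------------------------------------------------------------------

def fit_ellipse(contour: Contour | np.ndarray) -> EllipseParams:
    """Direct least-squares ellipse fit to a contour (>= 5 points)."""
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    return geometry.fit_ellipse_direct(pts)


def fuse_landmarks(ellipse: EllipseParams, landmarks: Landmarks,
                   contour: Contour) -> EllipseParams:
    """Refit the ellipse with the four manual landmarks as heavy anchors.

    Weighted least squares over the contour points plus the landmarks, each
    landmark weighted as ``LANDMARK_WEIGHT`` contour points, so the fit's
    extremes move toward the operator's marks without discarding the
    segmented contour. When the landmarks already lie on ``ellipse`` (and
    the contour does too) the fit is a fixed point.
    """
    if not isinstance(landmarks, Landmarks):
        raise InvalidLandmarksError("landmarks must be a Landmarks instance")
    pts = np.vstack([contour.points, landmarks.as_array()])
    wts = np.concatenate([
        np.ones(len(contour.points)),
        np.full(4, LANDMARK_WEIGHT),
    ])
    return geometry.fit_ellipse_direct(pts, weights=wts)


def ellipse_perimeter_cm(a_cm: float, b_cm: float) -> float:
    """Circumference of an ellipse with semi-axes in cm (Ramanujan II)."""
    return geometry.ellipse_perimeter_ramanujan(a_cm, b_cm)


def contour_arc_length_px(contour: Contour) -> float:
    """Polygonal arc length of the raw contour (diagnostic; overestimates)."""
    pts = contour.points
    seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def measure_hc(image: np.ndarray, landmarks: Landmarks, known_diameter_cm: float,
               color_spec: ColorSpec = BLUE_REFERENCE) -> HCMeasurement:
    """Measure head circumference in cm from one photograph.

    Composes segmentation, ellipse fitting, landmark fusion and scale
    calibration; the circumference is the Ramanujan-II perimeter of the
    fused ellipse after converting its semi-axes to cm.
    """
    contour = segment_head(image)
    initial = fit_ellipse(contour)
    fused = fuse_landmarks(initial, landmarks, contour)
    scale = detect_reference(image, known_diameter_cm, color_spec)

    pts = np.vstack([contour.points, landmarks.as_array()])
    wts = np.concatenate([np.ones(len(contour.points)), np.full(4, LANDMARK_WEIGHT)])
    quality = geometry.rms_residual(fused, pts, wts)

    a_cm = fused.a_px / scale.px_per_cm
    b_cm = fused.b_px / scale.px_per_cm
    hc = ellipse_perimeter_cm(a_cm, b_cm)
    warnings = []
    if scale.circularity < 0.92:
        warnings.append(
            f"reference circularity {scale.circularity:.3f} is low; "
            "scale may be imprecise")
    if quality > 0.02 * fused.b_px:
        warnings.append(
            f"ellipse fit residual {quality:.2f} px is large relative to the head")
    return HCMeasurement(
        hc_cm=float(hc),
        method="app",
        quality=float(quality),
        ellipse=fused,
        scale=scale,
        arc_length_cm=contour_arc_length_px(contour) / scale.px_per_cm,
        warnings=warnings,
    )
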