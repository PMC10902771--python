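"""Synthetic phantoms: rendered head photographs and simulated rater studies.

Nothing in a clinical head-circumference study can be redistributed, so the
toolkit carries its own ground truth. Two generators live here:

* :func:`render_phantom` draws a desk-scale stand-in for the clinic
  photograph — a skin-tone head ellipse with speckled "hair" texture and an
  anti-aliased boundary, a saturated blue reference disc of known physical
  diameter, optional gray distractor polygons, and Gaussian pixel noise —
  and returns the exact :class:`GroundTruth` (true circumference, rendered
  ellipse, the four landmark points, scale).

* :func:`simulate_rater_study` draws a long-format measurement table from
  the classical two-way reliability model ``HC_ijr = T_i + b_j + e_ijr``
  with subject effects ``T_i ~ N(mu, sigma_s^2)``, fixed per-rater biases
  ``b_j`` and rater-specific errors ``e_ijr ~ N(0, sigma_j^2)``, so the
  downstream ICC/agreement estimators can be checked against closed-form
  variance-component truths.

Both are deterministic given their integer seed.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InvalidSpecError
from .geometry import (
    EllipseParams,
    ellipse_perimeter_quadrature,
    point_to_ellipse_distance,
)
from .vision import Landmarks

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "RaterSpec",
    "RaterStudySpec",
    "render_phantom",
    "simulate_rater_study",
    "write_phantom",
    "load_phantom",
    "load_ground_truth",
]

_SUPERSAMPLE = 4  # subpixels per pixel per axis for anti-aliasing
_BACKGROUND_RGB = (212, 208, 202)
_HEAD_RGB = (205, 160, 110)  # skin tone
_SPECKLE_SD = 0.05  # multiplicative "hair" texture amplitude on the head


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one rendered phantom photograph.

    Geometry is specified in cm in a world frame whose origin coincides with
    the image origin (top-left pixel center, x rightward, y downward);
    ``scale_px_per_cm`` maps it to pixels. ``foreshorten`` models a small
    out-of-plane camera tilt as a multiplicative shortening of the rendered
    minor axis; the true circumference always refers to the untilted head.
    """

    image_width_px: int = 800
    image_height_px: int = 600
    head_center_cm: tuple = (17.5, 15.0)
    head_semi_major_cm: float = 7.5
    head_semi_minor_cm: float = 6.0
    head_rotation_deg: float = 0.0
    ref_center_cm: tuple = (33.0, 5.0)
    ref_diameter_cm: float = 3.0
    scale_px_per_cm: float = 20.0
    noise_sd: float = 2.0
    clutter_count: int = 0
    seed: int = 0
    foreshorten: float = 1.0
    ref_color_rgb: tuple = (30, 60, 200)

    def validate(self) -> None:
        problems = []
        if self.image_width_px < 1 or self.image_height_px < 1:
            problems.append("image dimensions must be positive")
        if not (self.head_semi_major_cm >= self.head_semi_minor_cm > 0):
            problems.append("head semi-axes must satisfy major >= minor > 0")
        if not (0.0 <= self.head_rotation_deg < 180.0):
            problems.append("head_rotation_deg must lie in [0, 180)")
        if self.ref_diameter_cm <= 0:
            problems.append("ref_diameter_cm must be positive")
        if self.scale_px_per_cm <= 0:
            problems.append("scale_px_per_cm must be positive")
        if self.noise_sd < 0:
            problems.append("noise_sd must be non-negative")
        if self.clutter_count < 0:
            problems.append("clutter_count must be non-negative")
        if not (0.5 <= self.foreshorten <= 1.0):
            problems.append("foreshorten must lie in [0.5, 1]")
        if self.ref_diameter_cm * self.scale_px_per_cm < 20:
            problems.append("reference must span >= 20 px to be resolvable")
        if problems:
            raise InvalidSpecError("; ".join(problems))

        ell = self.rendered_ellipse_px()
        margin = 2.0
        ext = ell.extremal_points()
        for name, (x, y) in ext.items():
            if not (margin <= x <= self.image_width_px - 1 - margin
                    and margin <= y <= self.image_height_px - 1 - margin):
                raise InvalidSpecError(
                    f"head ellipse extends outside the image near its {name} edge")
        rc = np.array(self.ref_center_cm) * self.scale_px_per_cm
        rr = self.ref_diameter_cm * self.scale_px_per_cm / 2.0
        if not (rc[0] - rr >= margin and rc[0] + rr <= self.image_width_px - 1 - margin
                and rc[1] - rr >= margin
                and rc[1] + rr <= self.image_height_px - 1 - margin):
            raise InvalidSpecError("reference disc extends outside the image")
        gap = point_to_ellipse_distance(ell, rc) - rr
        inside = (self._head_quadform(rc[0], rc[1]) <= 1.0)
        if inside or gap < 4.0:
            raise InvalidSpecError("head ellipse and reference disc overlap")

    def rendered_ellipse_px(self) -> EllipseParams:
        """The head ellipse as actually drawn, in pixel units."""
        s = self.scale_px_per_cm
        return EllipseParams.canonical(
            self.head_center_cm[0] * s,
            self.head_center_cm[1] * s,
            self.head_semi_major_cm * s,
            self.head_semi_minor_cm * self.foreshorten * s,
            math.radians(self.head_rotation_deg),
        )

    def _head_quadform(self, x, y):
        e = self.rendered_ellipse_px()
        ct, st = math.cos(e.theta_rad), math.sin(e.theta_rad)
        dx, dy = x - e.cx_px, y - e.cy_px
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / e.a_px) ** 2 + (v / e.b_px) ** 2


@dataclass(frozen=True)
class GroundTruth:
    """Exact truth for one rendered phantom."""

    true_hc_cm: float
    ellipse_px: EllipseParams
    landmarks_px: Landmarks
    ref_diameter_px: float
    scale_px_per_cm: float

    def to_dict(self) -> dict:
        e = self.ellipse_px
        lm = self.landmarks_px
        return {
            "true_hc_cm": self.true_hc_cm,
            "ellipse_px": {"cx_px": e.cx_px, "cy_px": e.cy_px, "a_px": e.a_px,
                           "b_px": e.b_px, "theta_rad": e.theta_rad},
            "landmarks_px": {"top": list(lm.top), "bottom": list(lm.bottom),
                             "lateral_left": list(lm.lateral_left),
                             "lateral_right": list(lm.lateral_right)},
            "ref_diameter_px": self.ref_diameter_px,
            "scale_px_per_cm": self.scale_px_per_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        e = d["ellipse_px"]
        lm = d["landmarks_px"]
        return cls(
            true_hc_cm=float(d["true_hc_cm"]),
            ellipse_px=EllipseParams(e["cx_px"], e["cy_px"], e["a_px"],
                                     e["b_px"], e["theta_rad"]),
            landmarks_px=Landmarks(top=tuple(lm["top"]), bottom=tuple(lm["bottom"]),
                                   lateral_left=tuple(lm["lateral_left"]),
                                   lateral_right=tuple(lm["lateral_right"])),
            ref_diameter_px=float(d["ref_diameter_px"]),
            scale_px_per_cm=float(d["scale_px_per_cm"]),
        )


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def _coverage_bbox(shape_test, width, height, bbox):
    """Anti-aliased coverage of an implicit shape, computed on a bbox only.

    ``shape_test(x, y) -> bool array`` takes pixel-frame coordinates.
    Returns (alpha array, (y0, y1, x0, x1)) with alpha in [0, 1].
    """
    s = _SUPERSAMPLE
    x0 = max(0, int(math.floor(bbox[0])))
    x1 = min(width, int(math.ceil(bbox[1])) + 1)
    y0 = max(0, int(math.floor(bbox[2])))
    y1 = min(height, int(math.ceil(bbox[3])) + 1)
    if x1 <= x0 or y1 <= y0:
        return np.zeros((0, 0)), (0, 0, 0, 0)
    # subpixel centers: pixel j covers [j-0.5, j+0.5]
    xs = x0 - 0.5 + (np.arange((x1 - x0) * s) + 0.5) / s
    ys = y0 - 0.5 + (np.arange((y1 - y0) * s) + 0.5) / s
    X, Y = np.meshgrid(xs.astype(np.float32), ys.astype(np.float32))
    inside = shape_test(X, Y)
    alpha = inside.reshape(y1 - y0, s, x1 - x0, s).mean(axis=(1, 3))
    return alpha, (y0, y1, x0, x1)


def _blend(img, alpha, window, color):
    y0, y1, x0, x1 = window
    if alpha.size == 0:
        return
    a = alpha[..., None]
    img[y0:y1, x0:x1] = (1.0 - a) * img[y0:y1, x0:x1] + a * np.asarray(color, float)


def _ellipse_test(e: EllipseParams):
    ct, st = math.cos(e.theta_rad), math.sin(e.theta_rad)

    def test(X, Y):
        dx, dy = X - e.cx_px, Y - e.cy_px
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / e.a_px) ** 2 + (v / e.b_px) ** 2 <= 1.0

    return test


def _polygon_test(verts: np.ndarray):
    # convex polygon, vertices counter-clockwise: inside iff left of all edges
    def test(X, Y):
        inside = np.ones(X.shape, dtype=bool)
        n = len(verts)
        for i in range(n):
            x1, y1 = verts[i]
            x2, y2 = verts[(i + 1) % n]
            cross = (x2 - x1) * (Y - y1) - (y2 - y1) * (X - x1)
            inside &= cross >= 0
        return inside

    return test


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a phantom photograph and its exact ground truth.

    Deterministic: identical specs (including seed) yield byte-identical
    images. Raises :class:`InvalidSpecError` when the geometry leaves the
    frame or the head and reference overlap.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    W, H = spec.image_width_px, spec.image_height_px
    img = np.empty((H, W, 3), dtype=float)
    img[:] = _BACKGROUND_RGB

    ell = spec.rendered_ellipse_px()
    ref_c = np.array(spec.ref_center_cm) * spec.scale_px_per_cm
    ref_r = spec.ref_diameter_cm * spec.scale_px_per_cm / 2.0

    # distractor clutter: convex gray polygons kept clear of head and reference
    head_r = max(ell.a_px, ell.b_px)
    for _ in range(spec.clutter_count):
        for _attempt in range(200):
            cx = rng.uniform(0.05 * W, 0.95 * W)
            cy = rng.uniform(0.05 * H, 0.95 * H)
            radius = rng.uniform(18.0, 45.0)
            d_head = math.hypot(cx - ell.cx_px, cy - ell.cy_px)
            d_ref = math.hypot(cx - ref_c[0], cy - ref_c[1])
            if (d_head > head_r + radius + 12 and d_ref > ref_r + radius + 12
                    and radius + 2 < cx < W - radius - 2
                    and radius + 2 < cy < H - radius - 2):
                break
        else:
            continue
        n_vert = int(rng.integers(3, 7))
        angles = np.sort(rng.uniform(0, 2 * math.pi, n_vert))
        radii = rng.uniform(0.45, 1.0, n_vert) * radius
        verts = np.column_stack([cx + radii * np.cos(angles),
                                 cy + radii * np.sin(angles)])
        gray = rng.uniform(95, 150)
        alpha, win = _coverage_bbox(
            _polygon_test(verts), W, H,
            (verts[:, 0].min(), verts[:, 0].max(),
             verts[:, 1].min(), verts[:, 1].max()))
        _blend(img, alpha, win, (gray, gray, gray))

    # head with multiplicative speckle ("hair" texture)
    ext = ell.extremal_points()
    bbox = (ext["lateral_left"][0], ext["lateral_right"][0],
            ext["top"][1], ext["bottom"][1])
    alpha, win = _coverage_bbox(_ellipse_test(ell), W, H, bbox)
    y0, y1, x0, x1 = win
    speckle = 1.0 + _SPECKLE_SD * rng.standard_normal((y1 - y0, x1 - x0))
    head_patch = np.clip(np.asarray(_HEAD_RGB, float) * speckle[..., None], 0, 255)
    a = alpha[..., None]
    img[y0:y1, x0:x1] = (1.0 - a) * img[y0:y1, x0:x1] + a * head_patch

    # reference disc
    def disc(X, Y):
        return (X - ref_c[0]) ** 2 + (Y - ref_c[1]) ** 2 <= ref_r**2

    alpha, win = _coverage_bbox(disc, W, H,
                                (ref_c[0] - ref_r, ref_c[0] + ref_r,
                                 ref_c[1] - ref_r, ref_c[1] + ref_r))
    _blend(img, alpha, win, spec.ref_color_rgb)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ext = ell.extremal_points()
    gt = GroundTruth(
        true_hc_cm=ellipse_perimeter_quadrature(
            spec.head_semi_major_cm, spec.head_semi_minor_cm),
        ellipse_px=ell,
        landmarks_px=Landmarks(top=ext["top"], bottom=ext["bottom"],
                               lateral_left=ext["lateral_left"],
                               lateral_right=ext["lateral_right"]),
        ref_diameter_px=spec.ref_diameter_cm * spec.scale_px_per_cm,
        scale_px_per_cm=spec.scale_px_per_cm,
    )
    return out, gt


# ---------------------------------------------------------------------------
# phantom I/O: PNG + JSON sidecar with the same basename
# ---------------------------------------------------------------------------

def write_phantom(path, image: np.ndarray, truth: GroundTruth) -> tuple[Path, Path]:
    """Write ``<path>.png`` and the ground-truth sidecar ``<path>.json``."""
    base = Path(path)
    if base.suffix.lower() == ".png":
        base = base.with_suffix("")
    png = base.with_suffix(".png")
    js = base.with_suffix(".json")
    Image.fromarray(image, mode="RGB").save(png)
    js.write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")
    return png, js


def load_phantom(path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG or JPEG) as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def load_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# simulated rater studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RaterSpec:
    """One rater arm: fixed bias and its own measurement-error SD (cm)."""

    rater_id: str
    bias_cm: float = 0.0
    error_sd_cm: float = 0.5
    method: str = "app"


@dataclass(frozen=True)
class RaterStudySpec:
    """Design of a simulated repeated-measures HC study.

    Defaults emulate an infant cohort: true circumferences
    ``N(45 cm, 2 cm^2)`` (the HC range of the first year and a half of
    life), two raters, one repeat.
    """

    n_subjects: int = 37
    subject_mean_cm: float = 45.0
    subject_sd_cm: float = 2.0
    raters: tuple = (RaterSpec("R1"), RaterSpec("R2"))
    n_repeats: int = 1
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if not self.raters:
            problems.append("at least one rater is required")
        if self.subject_sd_cm < 0:
            problems.append("subject_sd_cm must be non-negative")
        if self.n_repeats < 1:
            problems.append("n_repeats must be >= 1")
        for r in self.raters:
            if r.error_sd_cm < 0:
                problems.append(f"rater {r.rater_id}: error_sd_cm must be >= 0")
        if problems:
            raise InvalidSpecError("; ".join(problems))

    @property
    def true_icc(self) -> float:
        """Closed-form ICC(2,1) implied by the generating variance components.

        sigma_s^2 / (sigma_s^2 + sigma_b^2 + mean sigma_e^2), with the rater
        biases contributing their population variance sigma_b^2.
        """
        vs = self.subject_sd_cm**2
        biases = np.array([r.bias_cm for r in self.raters])
        vb = float(np.var(biases))  # fixed biases enter as rater variance
        ve = float(np.mean([r.error_sd_cm**2 for r in self.raters]))
        return vs / (vs + vb + ve)


def simulate_rater_study(spec: RaterStudySpec) -> pd.DataFrame:
    """Draw a long-format measurement table from the two-way additive model.

    Columns ``subject_id, rater_id, method, repeat, hc_cm``; repeats are
    numbered from 1. Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = rng.normal(spec.subject_mean_cm, spec.subject_sd_cm, spec.n_subjects)
    width = max(3, len(str(spec.n_subjects)))
    rows = []
    for i, t in enumerate(truth):
        sid = f"S{i + 1:0{width}d}"
        for r in spec.raters:
            errs = rng.normal(0.0, r.error_sd_cm, spec.n_repeats)
            for rep in range(spec.n_repeats):
                rows.append((sid, r.rater_id, r.method, rep + 1,
                             t + r.bias_cm + errs[rep]))
    return pd.DataFrame(rows, columns=["subject_id", "rater_id", "method",
                                       "repeat", "hc_cm"])
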