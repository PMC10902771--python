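"""Ellipse geometry: parameters, perimeters, sampling, and direct fitting.

The head contour is modelled as an ellipse throughout. This module holds the
shared primitives: the canonical ``EllipseParams`` container (pixel units,
origin at the top-left pixel center, x rightward, y downward, angles
counter-clockwise from +x), the Ramanujan-II closed-form perimeter used by the
measurement pipeline, an adaptive-quadrature perimeter used as the exact
reference, and a numerically stable direct least-squares conic fit with
optional per-point weights (the weights carry the manual-landmark fusion).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .errors import FitFailureError, InvalidArgumentError

__all__ = [
    "EllipseParams",
    "ellipse_perimeter_ramanujan",
    "ellipse_perimeter_quadrature",
    "fit_ellipse_direct",
    "conic_from_params",
    "sampson_distances",
    "rms_residual",
    "point_to_ellipse_distance",
]


@dataclass(frozen=True)
class EllipseParams:
    """Center, semi-axes and rotation of an ellipse in pixel coordinates.

    Invariants: ``a_px >= b_px > 0`` and ``theta_rad`` in ``[0, pi)``.
    Use :meth:`canonical` to build from unordered axes / unwrapped angles.
    """

    cx_px: float
    cy_px: float
    a_px: float
    b_px: float
    theta_rad: float

    def __post_init__(self):
        if not (self.a_px >= self.b_px > 0):
            raise InvalidArgumentError(
                f"semi-axes must satisfy a >= b > 0, got a={self.a_px}, b={self.b_px}"
            )
        if not (0.0 <= self.theta_rad < math.pi):
            raise InvalidArgumentError(
                f"theta must lie in [0, pi), got {self.theta_rad}"
            )

    @classmethod
    def canonical(cls, cx, cy, a, b, theta) -> "EllipseParams":
        """Build with axes ordered a >= b and theta wrapped into [0, pi)."""
        if a < b:
            a, b = b, a
            theta = theta + math.pi / 2.0
        theta = theta % math.pi
        if theta >= math.pi:  # guard fp wrap at the boundary
            theta -= math.pi
        return cls(float(cx), float(cy), float(a), float(b), float(theta))

    # -- sampling -------------------------------------------------------

    def point(self, t):
        """Boundary point(s) at parametric angle(s) ``t``."""
        t = np.asarray(t, dtype=float)
        ct, st = np.cos(self.theta_rad), np.sin(self.theta_rad)
        x = self.cx_px + self.a_px * np.cos(t) * ct - self.b_px * np.sin(t) * st
        y = self.cy_px + self.a_px * np.cos(t) * st + self.b_px * np.sin(t) * ct
        return np.stack([x, y], axis=-1)

    def sample(self, n: int = 360) -> np.ndarray:
        """``n`` boundary points, uniform in the parametric angle."""
        return self.point(np.linspace(0.0, 2.0 * math.pi, n, endpoint=False))

    def extremal_points(self) -> dict:
        """Topmost / bottommost / leftmost / rightmost boundary points.

        "Top" is minimal y (image convention: y grows downward).
        """
        a, b, th = self.a_px, self.b_px, self.theta_rad
        # dx/dt = 0  =>  tan t = -b sin(th) / (a cos(th))
        tx = math.atan2(-b * math.sin(th), a * math.cos(th))
        # dy/dt = 0  =>  tan t =  b cos(th) / (a sin(th))
        ty = math.atan2(b * math.cos(th), a * math.sin(th))
        px = self.point(np.array([tx, tx + math.pi]))
        py = self.point(np.array([ty, ty + math.pi]))
        left, right = sorted(px, key=lambda p: p[0])
        top, bottom = sorted(py, key=lambda p: p[1])
        return {
            "top": tuple(top),
            "bottom": tuple(bottom),
            "lateral_left": tuple(left),
            "lateral_right": tuple(right),
        }


# ---------------------------------------------------------------------------
# Perimeters
# ---------------------------------------------------------------------------

def _check_axes(a: float, b: float) -> None:
    if a < 0 or b < 0:
        raise InvalidArgumentError(f"semi-axes must be non-negative, got a={a}, b={b}")
    if a < b:
        raise InvalidArgumentError(f"expected a >= b, got a={a}, b={b}")
    if a == 0:
        raise InvalidArgumentError("major semi-axis must be positive")


def ellipse_perimeter_ramanujan(a: float, b: float) -> float:
    """Ramanujan's second perimeter approximation.

    With ``h = ((a-b)/(a+b))^2``::

        P = pi (a + b) (1 + 3h / (10 + sqrt(4 - 3h)))

    Accurate to well below 0.001% relative error for aspect ratios up to
    head-like values (a/b <= 3). ``b = 0`` is permitted as a degenerate
    check (true perimeter 4a; Ramanujan II gives ~3.9984a).
    """
    _check_axes(a, b)
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def ellipse_perimeter_quadrature(a: float, b: float) -> float:
    """Exact perimeter by adaptive quadrature of the arc-length integral.

    ``P = 4 * integral_0^{pi/2} sqrt(a^2 sin^2 t + b^2 cos^2 t) dt``.
    Used for phantom ground truth and as the reference the closed-form
    approximation is judged against.
    """
    _check_axes(a, b)
    val, _ = integrate.quad(
        lambda t: math.hypot(a * math.sin(t), b * math.cos(t)),
        0.0,
        math.pi / 2.0,
        epsabs=1e-13,
        epsrel=1e-13,
        limit=200,
    )
    return 4.0 * val


# ---------------------------------------------------------------------------
# Conic representation and residuals
# ---------------------------------------------------------------------------

def conic_from_params(e: EllipseParams) -> np.ndarray:
    """Coefficients (A, B, C, D, E, F) of Ax^2+Bxy+Cy^2+Dx+Ey+F = 0."""
    ct, st = math.cos(e.theta_rad), math.sin(e.theta_rad)
    a2, b2 = e.a_px**2, e.b_px**2
    A = ct**2 / a2 + st**2 / b2
    B = 2.0 * ct * st * (1.0 / a2 - 1.0 / b2)
    C = st**2 / a2 + ct**2 / b2
    # shift center
    cx, cy = e.cx_px, e.cy_px
    D = -2.0 * A * cx - B * cy
    E = -B * cx - 2.0 * C * cy
    F = A * cx**2 + B * cx * cy + C * cy**2 - 1.0
    return np.array([A, B, C, D, E, F])


def sampson_distances(coeffs: np.ndarray, points: np.ndarray) -> np.ndarray:
    """First-order geometric (Sampson) distance of points to a conic."""
    A, B, C, D, E, F = coeffs
    x, y = points[:, 0], points[:, 1]
    f = A * x**2 + B * x * y + C * y**2 + D * x + E * y + F
    gx = 2.0 * A * x + B * y + D
    gy = B * x + 2.0 * C * y + E
    g = np.hypot(gx, gy)
    g = np.where(g > 0, g, np.finfo(float).tiny)
    return np.abs(f) / g


def rms_residual(e: EllipseParams, points: np.ndarray, weights=None) -> float:
    """Weighted RMS Sampson distance of points to the ellipse, in px."""
    d = sampson_distances(conic_from_params(e), np.asarray(points, dtype=float))
    if weights is None:
        return float(np.sqrt(np.mean(d**2)))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt(np.sum(w * d**2) / np.sum(w)))


def point_to_ellipse_distance(e: EllipseParams, point, n: int = 2048) -> float:
    """Distance from a point to the ellipse boundary (dense-sampling minimum)."""
    pts = e.sample(n)
    d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1])
    return float(d.min())


# ---------------------------------------------------------------------------
# Direct least-squares ellipse fit (numerically stable, weighted)
# ---------------------------------------------------------------------------

def fit_ellipse_direct(points: np.ndarray, weights=None) -> EllipseParams:
    """Ellipse-constrained direct least-squares conic fit.

    The stable two-block formulation of the classic direct fit: the quadratic
    part of the scatter matrix is separated from the linear part so the
    ellipse constraint 4AC - B^2 = 1 reduces to a 3x3 eigenproblem with
    exactly one admissible eigenvector. Optional per-point ``weights`` act as
    multiplicities, which is how manual landmarks are given extra pull.

    Raises :class:`FitFailureError` for fewer than 5 points or degenerate
    (e.g. collinear) configurations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise FitFailureError(
            f"ellipse fit needs >= 5 two-dimensional points, got shape {pts.shape}"
        )
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(pts),) or np.any(w < 0) or not np.any(w > 0):
            raise FitFailureError("weights must be non-negative, one per point")

    # center & scale for conditioning
    mean = np.average(pts, axis=0, weights=w)
    xy = pts - mean
    scale = np.sqrt(np.average(xy**2, weights=np.repeat(w, 2).reshape(-1, 2)))
    if scale == 0:
        raise FitFailureError("all points coincide")
    xy = xy / scale
    x, y = xy[:, 0], xy[:, 1]

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    W = w[:, None]
    S1 = D1.T @ (W * D1)
    S2 = D1.T @ (W * D2)
    S3 = D2.T @ (W * D2)
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise FitFailureError("degenerate point configuration") from exc
    M = S1 + S2 @ T
    # premultiply by inv(C1) with C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    try:
        eigval, eigvec = np.linalg.eig(M)
    except np.linalg.LinAlgError as exc:
        raise FitFailureError("eigen decomposition failed") from exc
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    good = np.where(np.isreal(eigval) & (cond > 0))[0]
    if len(good) == 0:
        raise FitFailureError("no ellipse solution (degenerate or collinear input)")
    a1 = np.real(eigvec[:, good[0]])
    coeffs_n = np.concatenate([a1, T @ a1])  # in normalized frame

    # un-normalize: x_n = (x - mx)/s
    A, B, C, D, E, F = coeffs_n
    s, mx, my = scale, mean[0], mean[1]
    A2, B2, C2 = A / s**2, B / s**2, C / s**2
    D2_ = -2 * A * mx / s**2 - B * my / s**2 + D / s
    E2_ = -B * mx / s**2 - 2 * C * my / s**2 + E / s
    F2_ = (
        A * mx**2 / s**2
        + B * mx * my / s**2
        + C * my**2 / s**2
        - D * mx / s
        - E * my / s
        + F
    )
    return _params_from_conic(np.array([A2, B2, C2, D2_, E2_, F2_]))


def _params_from_conic(coeffs: np.ndarray) -> EllipseParams:
    A, B, C, D, E, F = coeffs
    den = B * B - 4.0 * A * C
    if den >= 0:
        raise FitFailureError("conic is not an ellipse")
    cx = (2.0 * C * D - B * E) / den
    cy = (2.0 * A * E - B * D) / den
    # centered constant term
    F0 = A * cx**2 + B * cx * cy + C * cy**2 + D * cx + E * cy + F
    M2 = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(M2)
    rhs = -F0
    if rhs == 0 or np.any(lam * np.sign(rhs) <= 0):
        raise FitFailureError("degenerate ellipse (zero area)")
    axes = np.sqrt(rhs / lam)  # lam ascending -> axes descending
    a_ax, b_ax = float(axes[0]), float(axes[1])
    major_vec = vec[:, 0]  # eigenvector of the smaller eigenvalue = major axis
    theta = math.atan2(major_vec[1], major_vec[0])
    return EllipseParams.canonical(cx, cy, a_ax, b_ax, theta)
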