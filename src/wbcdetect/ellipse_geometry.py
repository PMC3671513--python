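"""Ellipse geometry: five-point conic fitting and midpoint rasterization.

An ellipse candidate is built from five edge pixels.  The conic through the
five points is solved as a linear system, converted to center/axes/orientation
form, and rasterized into its "virtual shape" — the set of integer perimeter
pixels chosen by the midpoint ellipse algorithm (MEA), which tests the sign of
the ellipse function at inter-pixel midpoints and is therefore accurate to
half a pixel spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCandidateError, NonEllipseError, TooSmallError

__all__ = [
    "ConicCoefficients",
    "EllipseParams",
    "VirtualShape",
    "fit_conic",
    "conic_to_ellipse",
    "mea_rasterize",
    "ellipse_sign",
]

#: condition-number ceiling for the five-point linear system
_COND_LIMIT = 1e10
#: |C| below this is treated as a degenerate (parabolic) conic
_C_EPS = 1e-12
#: half-width of the "on the boundary" band for ellipse_sign
_SIGN_EPS = 1e-9


@dataclass(frozen=True)
class ConicCoefficients:
    """Coefficients of the conic ``a x^2 + 2h xy + b y^2 + 2g x + 2f y + 1 = 0``."""

    a: float
    h: float
    b: float
    g: float
    f: float

    def evaluate(self, x: float, y: float) -> float:
        """Value of the conic polynomial at ``(x, y)`` (zero on the curve)."""
        return (
            self.a * x * x
            + 2.0 * self.h * x * y
            + self.b * y * y
            + 2.0 * self.g * x
            + 2.0 * self.f * y
            + 1.0
        )


@dataclass(frozen=True)
class EllipseParams:
    """Geometric ellipse: center, semi-axes (pixels) and orientation (radians).

    ``theta`` is the angle of the major axis, normalized to (-pi/2, pi/2].
    """

    x0: float
    y0: float
    rmax: float
    rmin: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.rmax >= self.rmin > 0):
            raise NonEllipseError(
                f"invalid axes rmax={self.rmax}, rmin={self.rmin}"
            )

    def boundary_point(self, t: float) -> tuple[float, float]:
        """Point at parametric angle ``t`` on the continuous boundary."""
        ct, st = math.cos(self.theta), math.sin(self.theta)
        u = self.rmax * math.cos(t)
        v = self.rmin * math.sin(t)
        return (self.x0 + u * ct - v * st, self.y0 + u * st + v * ct)


@dataclass(frozen=True)
class VirtualShape:
    """Integer perimeter pixels of a rasterized ellipse (deduplicated)."""

    pixels: np.ndarray  # (Ns, 2) int array of (x, y)

    @property
    def count(self) -> int:
        return int(self.pixels.shape[0])

    def as_set(self) -> set[tuple[int, int]]:
        return {(int(x), int(y)) for x, y in self.pixels}


def fit_conic(points) -> ConicCoefficients:
    """Fit the conic ``a x^2 + 2h xy + b y^2 + 2g x + 2f y + 1 = 0`` through five points.

    Solves the 5x5 linear system in (a, h, b, g, f) with the constant term
    fixed at one.  Columns are scaled to unit peak magnitude before solving so
    raw pixel coordinates (up to ~1e3) do not wreck the conditioning.

    Raises
    ------
    DegenerateCandidateError
        If the points are not distinct, are collinear, or otherwise leave the
        system singular or with condition number above 1e10.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (5, 2):
        raise DegenerateCandidateError(f"need exactly five (x, y) points, got {pts.shape}")
    if len({(px, py) for px, py in pts.tolist()}) < 5:
        raise DegenerateCandidateError("duplicate points among the five")

    x, y = pts[:, 0], pts[:, 1]
    m = np.column_stack([x * x, 2.0 * x * y, y * y, 2.0 * x, 2.0 * y])
    scale = np.max(np.abs(m), axis=0)
    scale[scale == 0] = 1.0
    ms = m / scale
    try:
        # 1-norm condition estimate: LU-based, much cheaper than the SVD
        if np.linalg.cond(ms, 1) > _COND_LIMIT:
            raise DegenerateCandidateError("ill-conditioned five-point system")
        sol = np.linalg.solve(ms, -np.ones(5)) / scale
    except np.linalg.LinAlgError as exc:
        raise DegenerateCandidateError("singular five-point system") from exc
    if not np.all(np.isfinite(sol)):
        raise DegenerateCandidateError("non-finite conic solution")
    a, h, b, g, f = sol
    return ConicCoefficients(a=float(a), h=float(h), b=float(b), g=float(g), f=float(f))


def conic_to_ellipse(c: ConicCoefficients) -> EllipseParams:
    """Convert conic coefficients to center/axes/orientation form.

    The conic is first normalized so that ``a + b < 0`` (multiplying the whole
    equation by -1 flips the constant term, which the discriminant matrix
    accounts for); this matches the circle closed form a = b = -1/r^2.  With

        C = a b - h^2,   R = sqrt((a - b)^2 + 4 h^2),
        Delta = det [[a, h, g], [h, b, f], [g, f, c0]],

    the center is ``((h f - b g)/C, (g h - a f)/C)`` and the squared semi-axes
    are ``-2 Delta / (C (a + b +/- R))``; the ``+R`` root pairs with the major
    axis, whose direction is ``theta = atan2(2h, a - b) / 2``.

    Raises
    ------
    NonEllipseError
        If ``C <= 0`` (hyperbola/parabola) or either squared-axis argument is
        not strictly positive (degenerate or imaginary ellipse).
    """
    a, h, b, g, f = c.a, c.h, c.b, c.g, c.f
    c0 = 1.0
    if a + b > 0:
        a, h, b, g, f, c0 = -a, -h, -b, -g, -f, -1.0

    cc = a * b - h * h
    if not np.isfinite(cc) or abs(cc) < _C_EPS or cc < 0:
        raise NonEllipseError(f"conic discriminant C={cc!r} does not describe an ellipse")

    x0 = (h * f - b * g) / cc
    y0 = (g * h - a * f) / cc
    rr = math.hypot(a - b, 2.0 * h)
    delta = float(np.linalg.det(np.array([[a, h, g], [h, b, f], [g, f, c0]])))

    denom_major = cc * (a + b + rr)
    denom_minor = cc * (a + b - rr)
    if denom_major == 0 or denom_minor == 0:
        raise NonEllipseError("degenerate conic: zero axis denominator")
    arg_major = -2.0 * delta / denom_major
    arg_minor = -2.0 * delta / denom_minor
    if arg_major <= 0 or arg_minor <= 0:
        raise NonEllipseError("imaginary or degenerate ellipse axes")

    rmax = math.sqrt(arg_major)
    rmin = math.sqrt(arg_minor)
    theta = 0.5 * math.atan2(2.0 * h, a - b)
    if rmax < rmin:  # numerical safety only; +R pairs with the major axis
        rmax, rmin = rmin, rmax
        theta += 0.5 * math.pi
    if theta > 0.5 * math.pi:
        theta -= math.pi
    elif theta <= -0.5 * math.pi:
        theta += math.pi
    return EllipseParams(x0=float(x0), y0=float(y0), rmax=rmax, rmin=rmin, theta=theta)


def ellipse_sign(x: float, y: float, e: EllipseParams) -> int:
    """Sign of the ellipse function at ``(x, y)``: -1 inside, 0 on, +1 outside.

    Evaluated in the ellipse-aligned frame as
    ``rmin^2 u^2 + rmax^2 v^2 - rmax^2 rmin^2`` with u along the major axis;
    values within 1e-9 of zero are reported as on the boundary.
    """
    ct, st = math.cos(e.theta), math.sin(e.theta)
    dx, dy = x - e.x0, y - e.y0
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    val = e.rmin**2 * u * u + e.rmax**2 * v * v - e.rmax**2 * e.rmin**2
    if abs(val) < _SIGN_EPS:
        return 0
    return -1 if val < 0 else 1


def _quadrant_arrays(ra: float, rb: float) -> tuple[np.ndarray, np.ndarray]:
    """First-quadrant midpoint walk for the axis-aligned ellipse u^2/ra^2 + v^2/rb^2 = 1.

    The quadrant is split where the boundary slope equals -1, at
    ``u* = ra^2 / sqrt(ra^2 + rb^2)``.  Region 1 steps column by column up to
    ``u*`` choosing each row by the sign of the ellipse function at the
    midpoint (u, v - 1/2); region 2 steps row by row from ``v*`` down to the
    major axis with midpoints (u + 1/2, v).  A midpoint exactly on the curve
    counts as outside (>= 0), fixing the tie convention.
    """
    a2 = ra * ra
    b2 = rb * rb

    def fe(u: float, v: float) -> float:
        return b2 * u * u + a2 * v * v - a2 * b2

    denom = math.sqrt(a2 + b2)
    u_split = a2 / denom  # column of the slope = -1 boundary point
    v_split = b2 / denom

    # region 1: for each column u, the largest row v with fe(u, v - 1/2) < 0,
    # which is ceil(v_real - 1/2); a sign fix-up enforces the midpoint tie
    # convention (midpoint exactly on the curve counts as outside) under
    # floating point.  Region 2 is symmetric, row by row.
    u1 = np.arange(0, math.floor(u_split) + 1)
    v1 = np.ceil(rb * np.sqrt(np.maximum(1.0 - u1 * u1 / a2, 0.0)) - 0.5).astype(int)
    v1 -= (fe(u1, v1 - 0.5) >= 0).astype(int)
    np.maximum(v1, 0, out=v1)

    v2 = np.arange(0, math.floor(v_split) + 1)
    u2 = np.ceil(ra * np.sqrt(np.maximum(1.0 - v2 * v2 / b2, 0.0)) - 0.5).astype(int)
    u2 -= (fe(u2 - 0.5, v2) >= 0).astype(int)
    np.maximum(u2, 0, out=u2)

    return np.concatenate([u1, u2]), np.concatenate([v1, v2])


def _quadrant_walk(ra: float, rb: float) -> list[tuple[int, int]]:
    """First-quadrant midpoint pixels as (u, v) tuples (convenience wrapper)."""
    u, v = _quadrant_arrays(ra, rb)
    return list(zip(u.tolist(), v.tolist()))


def mea_rasterize(e: EllipseParams, bounds: tuple[int, int]) -> VirtualShape:
    """Rasterize an ellipse perimeter with the midpoint ellipse algorithm.

    The axis-aligned quadrant walk is mirrored through both axes (4-fold
    symmetry), rotated by ``theta`` about the center, rounded to the integer
    grid and deduplicated.  Pixels outside ``bounds = (width, height)`` are
    discarded.  Output is deterministic and sorted in row-major order.

    Raises
    ------
    TooSmallError
        If either semi-axis is below one pixel.
    """
    if e.rmax < 1.0 or e.rmin < 1.0:
        raise TooSmallError(f"axes ({e.rmax}, {e.rmin}) below 1 px rasterization minimum")
    width, height = int(bounds[0]), int(bounds[1])

    qu, qv = _quadrant_arrays(e.rmax, e.rmin)
    u = np.concatenate([qu, -qu, qu, -qu])
    v = np.concatenate([qv, qv, -qv, -qv])

    ct, st = math.cos(e.theta), math.sin(e.theta)
    x = np.floor(e.x0 + u * ct - v * st + 0.5).astype(int)
    y = np.floor(e.y0 + u * st + v * ct + 0.5).astype(int)

    keep = (x >= 0) & (x < width) & (y >= 0) & (y < height)
    # dedupe via flat row-major keys; unique also yields row-major ordering
    keys = np.unique(y[keep] * width + x[keep])
    pix = np.column_stack([keys % width, keys // width])
    return VirtualShape(pixels=pix)
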