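"""Seeded smear-like test images with known ellipse ground truth.

Bright background, dark filled elliptical "leukocytes", optional small round
distractors standing in for red blood cells, plus the two corruption models
used in the robustness experiments: salt-and-pepper replacement noise and
additive Gaussian intensity noise (sigma on the 0-255 scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ellipse_geometry import EllipseParams
from .errors import ValidationError

__all__ = [
    "SceneSpec",
    "cell_interior_mask",
    "render_cells",
    "random_scene",
    "add_salt_pepper",
    "add_gaussian",
]


@dataclass(frozen=True)
class SceneSpec:
    """Scene description: cells, intensities, and distractor count."""

    cells: tuple[EllipseParams, ...]
    cell_intensity: float = 60.0
    background_intensity: float = 220.0
    distractor_count: int = 0
    distractor_intensity: float = 150.0
    distractor_radius: tuple[float, float] = (3.0, 6.0)
    jitter: float = 2.0  # per-pixel intensity jitter (std, gray levels)

    def __post_init__(self) -> None:
        for cell in self.cells:
            if cell.rmin < 3.0:
                raise ValidationError(f"cell rmin {cell.rmin} below the 3 px minimum")


def cell_interior_mask(e: EllipseParams, width: int, height: int) -> np.ndarray:
    """Boolean (H, W) mask of pixels inside or on the ellipse boundary."""
    yy, xx = np.mgrid[0:height, 0:width]
    ct, st = math.cos(e.theta), math.sin(e.theta)
    dx = xx - e.x0
    dy = yy - e.y0
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return (u / e.rmax) ** 2 + (v / e.rmin) ** 2 <= 1.0


def render_cells(
    spec: SceneSpec, width: int, height: int, seed: int = 0
) -> tuple[np.ndarray, list[EllipseParams]]:
    """Render the scene; returns the uint8 image and the ground-truth ellipses.

    Cells are painted over distractors, intensities carry mild seeded jitter,
    and a cell entirely outside the frame is a validation error.
    """
    rng = np.random.default_rng(seed)
    img = np.full((height, width), spec.background_intensity, dtype=float)
    img += rng.normal(0.0, spec.jitter, img.shape)

    for _ in range(spec.distractor_count):
        r = rng.uniform(*spec.distractor_radius)
        cx = rng.uniform(r, width - r)
        cy = rng.uniform(r, height - r)
        yy, xx = np.mgrid[0:height, 0:width]
        blob = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        img[blob] = spec.distractor_intensity + rng.normal(0.0, spec.jitter, int(blob.sum()))

    for cell in spec.cells:
        interior = cell_interior_mask(cell, width, height)
        if not interior.any():
            raise ValidationError(f"cell at ({cell.x0}, {cell.y0}) lies entirely outside the frame")
        img[interior] = spec.cell_intensity + rng.normal(0.0, spec.jitter, int(interior.sum()))

    return np.clip(np.rint(img), 0, 255).astype(np.uint8), list(spec.cells)


def random_scene(
    n_cells: int,
    width: int,
    height: int,
    seed: int = 0,
    rmax_range: tuple[float, float] = (10.0, 16.0),
    axis_ratio_range: tuple[float, float] = (0.6, 0.95),
    overlap: str = "none",
    distractor_count: int = 0,
) -> SceneSpec:
    """Draw a seeded random scene of ``n_cells`` ellipses inside the frame.

    ``overlap`` controls center spacing: "none" keeps cells separated by at
    least the sum of their major axes plus a margin, "touching" allows rims to
    meet, and "occluded" forces neighboring pairs closer than 1.2x rmax.
    """
    if overlap not in ("none", "touching", "occluded"):
        raise ValidationError(f"unknown overlap mode {overlap!r}")
    rng = np.random.default_rng(seed)
    cells: list[EllipseParams] = []
    attempts = 0
    while len(cells) < n_cells:
        attempts += 1
        if attempts > 5000:
            raise ValidationError("could not place cells; frame too small for the request")
        rmax = rng.uniform(*rmax_range)
        rmin = max(3.0, rmax * rng.uniform(*axis_ratio_range))
        margin = rmax + 2.0
        if width <= 2 * margin or height <= 2 * margin:
            raise ValidationError("frame too small for requested cell sizes")
        x0 = rng.uniform(margin, width - margin)
        y0 = rng.uniform(margin, height - margin)
        theta = rng.uniform(-math.pi / 2, math.pi / 2)
        cand = EllipseParams(x0=x0, y0=y0, rmax=rmax, rmin=rmin, theta=theta)
        if overlap == "occluded" and cells:
            ref = cells[-1]
            ang = rng.uniform(0, 2 * math.pi)
            d = 1.2 * max(ref.rmax, cand.rmax)
            x0 = min(max(ref.x0 + d * math.cos(ang), margin), width - margin)
            y0 = min(max(ref.y0 + d * math.sin(ang), margin), height - margin)
            cand = EllipseParams(x0=x0, y0=y0, rmax=rmax, rmin=rmin, theta=theta)
            cells.append(cand)
            continue
        min_gap = 4.0 if overlap == "none" else 0.0
        ok = all(
            math.hypot(c.x0 - cand.x0, c.y0 - cand.y0) >= c.rmax + cand.rmax + min_gap
            for c in cells
        )
        if ok:
            cells.append(cand)
    return SceneSpec(cells=tuple(cells), distractor_count=distractor_count)


def add_salt_pepper(image: np.ndarray, p: float, seed: int = 0) -> np.ndarray:
    """Replace each pixel independently with 0 or 255 (equal odds) with probability p."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"salt-and-pepper probability {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.asarray(image).astype(np.uint8).copy()
    hit = rng.random(out.shape) < p
    values = rng.integers(0, 2, size=out.shape).astype(np.uint8) * 255
    out[hit] = values[hit]
    return out


def add_gaussian(image: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Add zero-mean Gaussian noise of the given sigma (0-255 scale), clip and round."""
    if sigma < 0:
        raise ValidationError(f"sigma must be non-negative, got {sigma}")
    rng = np.random.default_rng(seed)
    out = np.asarray(image).astype(float) + rng.normal(0.0, sigma, np.asarray(image).shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
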