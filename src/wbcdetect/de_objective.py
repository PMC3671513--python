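"""Matching-error objective for candidate ellipses.

A candidate is five continuous index positions into the edge-pixel vector.
Decoding rounds and clamps the indices, the five pixels are fitted to a
conic, converted to an ellipse, rasterized, and the fraction of perimeter
pixels that coincide with edge pixels determines the score
``J = 1 - matches / Ns`` (0 = perfect fit).  Every degeneracy maps to the
worst score 1 so the optimizer's selection step stays total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ellipse_geometry import (
    EllipseParams,
    VirtualShape,
    conic_to_ellipse,
    fit_conic,
    mea_rasterize,
)
from .errors import (
    DegenerateCandidateError,
    NonEllipseError,
    TooSmallError,
)

__all__ = [
    "Candidate",
    "Fitness",
    "SizeLimits",
    "decode",
    "match_score",
    "evaluate_candidate",
    "candidate_to_ellipse",
]


@dataclass(frozen=True)
class Candidate:
    """Five real-valued gene positions indexing into an edge list."""

    genes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", np.asarray(self.genes, dtype=float))


@dataclass(frozen=True)
class Fitness:
    """Score of one candidate: ``value = 1 - matches/ns`` (1 when degenerate)."""

    value: float
    matches: int
    ns: int


WORST_FITNESS = Fitness(value=1.0, matches=0, ns=0)


@dataclass(frozen=True)
class SizeLimits:
    """Plausibility bounds on detected ellipse axes (pixels).

    ``max_rmax_fraction`` is relative to the shorter image side.  These are
    plumbing, not biology: they stop the optimizer from exploiting tiny
    ellipses that trivially match a few stray pixels.
    """

    min_rmin: float = 3.0
    max_rmax_fraction: float = 0.5

    def admits(self, e: EllipseParams, image_shape: tuple[int, int]) -> bool:
        """True if the ellipse axes are inside the limits for an HxW image."""
        max_rmax = self.max_rmax_fraction * min(image_shape)
        return e.rmin >= self.min_rmin and e.rmax <= max_rmax


def decode(cand: Candidate, edges) -> np.ndarray:
    """Map genes to five edge pixels: round to nearest index, clamp to [0, Np-1]."""
    np_count = edges.count
    idx = np.clip(np.rint(cand.genes).astype(int), 0, np_count - 1)
    return edges.points[idx]


def match_score(shape: VirtualShape, edge_mask: np.ndarray) -> Fitness:
    """Fraction of virtual-shape pixels present in the edge map, as ``J = 1 - hits/Ns``.

    An empty shape yields the worst fitness.
    """
    ns = shape.count
    if ns == 0:
        return WORST_FITNESS
    x = shape.pixels[:, 0]
    y = shape.pixels[:, 1]
    matches = int(np.count_nonzero(edge_mask[y, x]))
    return Fitness(value=1.0 - matches / ns, matches=matches, ns=ns)


def candidate_to_ellipse(
    cand: Candidate,
    edges,
    image_shape: tuple[int, int],
    limits: SizeLimits | None = None,
) -> EllipseParams | None:
    """Decode a candidate into an ellipse, or None for any degeneracy."""
    limits = limits or SizeLimits()
    pts = decode(cand, edges)
    if len({(px, py) for px, py in pts.tolist()}) < 5:
        return None
    try:
        ellipse = conic_to_ellipse(fit_conic(pts))
    except (DegenerateCandidateError, NonEllipseError):
        return None
    if not limits.admits(ellipse, image_shape):
        return None
    return ellipse


def evaluate_candidate(
    cand: Candidate,
    edges,
    edge_mask: np.ndarray,
    limits: SizeLimits | None = None,
) -> Fitness:
    """Full objective: decode -> fit -> convert -> rasterize -> match.

    Singular fits, non-ellipse conics, axes outside the size limits and
    unrasterizable shapes all score the worst fitness instead of raising.
    """
    height, width = edge_mask.shape
    ellipse = candidate_to_ellipse(cand, edges, (height, width), limits)
    if ellipse is None:
        return WORST_FITNESS
    try:
        shape = mea_rasterize(ellipse, (width, height))
    except TooSmallError:
        return WORST_FITNESS
    return match_score(shape, edge_mask)
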