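"""Smear-image preprocessing: segmentation, WBC mask and morphological edge map.

Segmentation is a diffused expectation-maximization (DEM) over a K-component
Gaussian intensity mixture: after every E-step each class-posterior map is
smoothed by one explicit anisotropic-diffusion update whose edge-stopping
diffusivity is a negative power of the posterior gradient magnitude, so class
membership is regularized across neighboring pixels before the M-step.  The
darkest resulting class is taken as the WBC (stained-nucleus) class, and the
edge map is the morphological inner boundary of that mask (mask minus its
3x3 erosion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .errors import DegenerateInputError, TooFewEdgesError, ValidationError

__all__ = [
    "DEMConfig",
    "LabelImage",
    "EdgeList",
    "dem_segment",
    "otsu3_segment",
    "select_wbc_mask",
    "morph_edge",
    "edges_to_list",
    "as_gray",
]

#: 3x3 all-ones structuring element used for the erosion-based edge map
_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class DEMConfig:
    """DEM segmentation settings.

    Defaults follow the calibrated configuration: K = 3 classes, diffusion
    step 0.1, 10 iterations, edge-stopping exponent -9/5 with the gradient
    magnitude floored at 1e-3 before exponentiation.
    """

    n_classes: int = 3
    diffusion_step: float = 0.1
    n_iterations: int = 10
    edge_stopping_exponent: float = -9.0 / 5.0
    gradient_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.diffusion_step <= 0:
            raise ValidationError("diffusion_step must be positive")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")


@dataclass(frozen=True)
class LabelImage:
    """Per-pixel class labels with class mean intensities sorted ascending."""

    labels: np.ndarray  # (H, W) int, values in {0..K-1}
    class_means: np.ndarray  # (K,) float, ascending

    @property
    def n_classes(self) -> int:
        return int(self.class_means.shape[0])


@dataclass(frozen=True)
class EdgeList:
    """Edge pixels as an ordered (row-major) vector of (x, y) coordinates."""

    points: np.ndarray  # (Np, 2) int, columns (x, y)
    shape: tuple[int, int]  # (H, W) of the source edge map

    @property
    def count(self) -> int:
        return int(self.points.shape[0])

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask[self.points[:, 1], self.points[:, 0]] = True
        return mask


def as_gray(image: np.ndarray) -> np.ndarray:
    """Coerce an 8-bit grayscale or RGB(A) image to a float grayscale array."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])
    else:
        arr = arr.astype(float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"expected a 2-D image, got shape {np.asarray(image).shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("image contains non-finite intensities")
    return arr


def _diffuse_once(h: np.ndarray, config: DEMConfig) -> np.ndarray:
    """One explicit anisotropic-diffusion step on a posterior map.

    Four-neighbor discretization with replicated borders (zero-flux);
    diffusivity g = max(|grad|, floor)^exponent per directional difference.
    The negative exponent makes g diverge as gradients shrink, so wherever the
    combined neighbor weight ``step * sum(g)`` exceeds one — the explicit
    stability limit — all four weights are rescaled to sum to one.  This keeps
    the scheme stable while preserving the relative edge-stopping profile
    (weak diffusion across strong posterior edges, strong within flat runs).
    The result is clipped back to [0, 1].
    """
    padded = np.pad(h, 1, mode="edge")
    flux = np.zeros_like(h)
    weight_sum = np.zeros_like(h)
    for ds, dr in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        diff = padded[1 + ds : h.shape[0] + 1 + ds, 1 + dr : h.shape[1] + 1 + dr] - h
        mag = np.maximum(np.abs(diff), config.gradient_floor)
        g = mag**config.edge_stopping_exponent
        flux += g * diff
        weight_sum += g
    weight_sum *= config.diffusion_step
    scale = np.where(weight_sum > 1.0, 1.0 / weight_sum, 1.0)
    return np.clip(h + scale * config.diffusion_step * flux, 0.0, 1.0)


def dem_segment(image: np.ndarray, config: DEMConfig | None = None, seed: int = 0) -> LabelImage:
    """Segment a grayscale image into K classes with diffused EM.

    Each iteration: E-step posteriors for the Gaussian mixture, one
    anisotropic-diffusion update per posterior map, per-pixel renormalization,
    then the M-step on the diffused posteriors.  Runs exactly
    ``config.n_iterations`` iterations; labels are the argmax of the final
    diffused posteriors, with classes relabeled by ascending mean intensity.

    Mixture means are initialized at evenly spaced intensity quantiles (the
    seed only perturbs them by a tiny jitter to break exact ties), so results
    are reproducible.

    Raises
    ------
    DegenerateInputError
        If the image is constant (no identifiable mixture).
    ValidationError
        If intensities are non-finite.
    """
    config = config or DEMConfig()
    gray = as_gray(image)
    values = gray.ravel()
    if np.unique(values).size < 2:
        raise DegenerateInputError("constant image: mixture is not identifiable")

    k = config.n_classes
    rng = np.random.default_rng(seed)
    quantiles = (np.arange(k) + 0.5) / k
    means = np.quantile(values, quantiles) + rng.normal(0.0, 1e-6, size=k)
    variances = np.full(k, max(values.var() / k, 1.0))
    weights = np.full(k, 1.0 / k)

    shape = gray.shape
    post = np.empty((k, *shape))
    for _ in range(config.n_iterations):
        # E-step: Gaussian mixture posteriors per pixel
        for j in range(k):
            post[j] = weights[j] * np.exp(
                -0.5 * (gray - means[j]) ** 2 / variances[j]
            ) / np.sqrt(2.0 * np.pi * variances[j])
        total = post.sum(axis=0)
        total[total < 1e-300] = 1e-300
        post /= total

        # diffuse each class-posterior map, then renormalize per pixel
        for j in range(k):
            post[j] = _diffuse_once(post[j], config)
        total = post.sum(axis=0)
        total[total <= 0] = 1.0
        post /= total

        # M-step from diffused posteriors
        sums = post.reshape(k, -1).sum(axis=1)
        sums = np.maximum(sums, 1e-12)
        weights = sums / values.size
        means = (post.reshape(k, -1) @ values) / sums
        for j in range(k):
            variances[j] = max(
                float((post[j].ravel() * (values - means[j]) ** 2).sum() / sums[j]), 1e-2
            )

    labels = np.argmax(post, axis=0)
    order = np.argsort(means)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return LabelImage(labels=relabel[labels], class_means=np.sort(means))


def otsu3_segment(image: np.ndarray, n_classes: int = 3) -> LabelImage:
    """Fast fallback: multilevel Otsu thresholding into ``n_classes`` classes."""
    gray = as_gray(image)
    if np.unique(gray).size < n_classes:
        raise DegenerateInputError("too few distinct intensities for multilevel thresholding")
    thresholds = threshold_multiotsu(gray, classes=n_classes)
    labels = np.digitize(gray, bins=thresholds)
    means = np.array(
        [gray[labels == j].mean() if np.any(labels == j) else np.nan for j in range(n_classes)]
    )
    return LabelImage(labels=labels, class_means=means)


def select_wbc_mask(labels: LabelImage, class_index: int | None = None) -> np.ndarray:
    """Binary mask of the WBC class (default: lowest mean intensity, index 0).

    Stained nuclei are the darkest structures, so the lowest-mean class is the
    conventional choice; pass ``class_index`` to override.  An empty class
    yields an empty mask and a warning.
    """
    if labels.n_classes < 2:
        raise ValidationError("need at least 2 classes to select a WBC class")
    idx = 0 if class_index is None else class_index
    mask = labels.labels == idx
    if not mask.any():
        warnings.warn(f"selected WBC class {idx} is empty", stacklevel=2)
    return mask


def morph_edge(mask: np.ndarray) -> np.ndarray:
    """Morphological edge map: ``mask AND NOT erosion(mask, 3x3 ones)``.

    Pixels beyond the image frame count as background, so mask pixels touching
    the frame are edges.
    """
    mask = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT_3X3, border_value=0)
    return mask & ~eroded


def edges_to_list(edge: np.ndarray) -> EdgeList:
    """Flatten an edge map into the edge vector P, scanning row-major.

    Raises
    ------
    TooFewEdgesError
        If fewer than five edge pixels exist (an ellipse needs five points).
    """
    edge = np.asarray(edge).astype(bool)
    rc = np.argwhere(edge)  # row-major sorted (y, x)
    if rc.shape[0] < 5:
        raise TooFewEdgesError(f"only {rc.shape[0]} edge pixels; at least 5 required")
    points = np.column_stack([rc[:, 1], rc[:, 0]]).astype(int)
    return EdgeList(points=points, shape=edge.shape)
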