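"""End-to-end WBC detector: preprocess -> repeated DE runs -> accept/mask -> report.

Multi-ellipse strategy is sequential detect-and-mask: each stage runs the DE
optimizer on the live edge list; an accepted ellipse is recorded and its
perimeter pixels (dilated by a small radius) are removed from the edge map so
the next stage cannot rediscover the same cell.  A stage fails after a fixed
number of restart attempts without an acceptable score, which ends the loop.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import remove_small_objects

from .de_engine import DEConfig, run_de
from .de_objective import Candidate, SizeLimits, candidate_to_ellipse, evaluate_candidate
from .ellipse_geometry import EllipseParams, mea_rasterize
from .errors import TooFewEdgesError, ValidationError
from .preprocess import (
    DEMConfig,
    as_gray,
    dem_segment,
    edges_to_list,
    morph_edge,
    otsu3_segment,
    select_wbc_mask,
)

__all__ = ["Detection", "DetectorConfig", "detect_wbc", "write_report", "read_report"]


@dataclass(frozen=True)
class Detection:
    """One accepted ellipse with its matching error and originating DE run."""

    ellipse: EllipseParams
    score: float
    run_index: int


@dataclass(frozen=True)
class DetectorConfig:
    """Detector plumbing around the DE core.

    ``accept_threshold`` sits slightly above the worked matching-error example
    of ~0.33 for a valid partially occluded ellipse.  ``n_restarts`` bounds
    how many fresh DE runs a stage may try before the stage counts as failed.
    ``min_region_area`` removes speckle components from the WBC mask before
    edge extraction (important under salt-and-pepper noise); set 0 to disable.

    A run's fate on the plateaued matching objective is decided within the
    first few dozen generations (it either assembles a five-point set on one
    cell boundary almost immediately or converges prematurely and never
    recovers), so the per-run generation budget here is shorter than the
    optimizer's single-run default and the stage budget is spent on restarts
    instead.  ``stop_below`` ends a run early once the score is clearly below
    the acceptance gate.
    """

    pop_size: int = 20
    scale_factor: float = 0.25
    crossover_rate: float = 0.80
    n_generations: int = 60
    accept_threshold: float = 0.35
    max_detections: int = 20
    mask_dilation: int = 2
    n_restarts: int = 16
    stop_below: float | None = 0.15
    min_region_area: int = 25
    segmenter: str = "dem"
    seed: int = 0
    limits: SizeLimits = field(default_factory=SizeLimits)
    dem: DEMConfig = field(default_factory=DEMConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.accept_threshold < 1.0):
            raise ValidationError("accept_threshold must lie in (0, 1)")
        if self.max_detections < 1:
            raise ValidationError("max_detections must be >= 1")
        if self.segmenter not in ("dem", "otsu3"):
            raise ValidationError(f"unknown segmenter {self.segmenter!r}")


def _segment_mask(gray: np.ndarray, config: DetectorConfig) -> np.ndarray:
    if config.segmenter == "otsu3":
        labels = otsu3_segment(gray, n_classes=config.dem.n_classes)
    else:
        labels = dem_segment(gray, config.dem, seed=config.seed)
    mask = select_wbc_mask(labels)
    if config.min_region_area > 0 and mask.any():
        # under impulse noise the WBC class picks up speckles (pepper) and
        # loses interior pixels (salt); drop tiny components and fill holes so
        # the edge map carries only outer cell boundaries
        mask = remove_small_objects(mask, max_size=config.min_region_area - 1)
        mask = ndimage.binary_fill_holes(mask)
    return mask


def detect_wbc(
    image: np.ndarray,
    config: DetectorConfig | None = None,
    edge_map: np.ndarray | None = None,
    return_log: bool = False,
):
    """Detect elliptical WBCs in a smear image.

    When ``edge_map`` is given, segmentation is skipped and the detector runs
    directly on that binary map.  Returns detections sorted by ascending
    matching error; with ``return_log=True`` also returns per-run best-score
    trajectories (list of ``(run_index, history)``).
    """
    config = config or DetectorConfig()
    gray = as_gray(image)
    height, width = gray.shape

    if edge_map is None:
        mask = _segment_mask(gray, config)
        edge = morph_edge(mask)
    else:
        edge = np.asarray(edge_map).astype(bool)
        if edge.shape != gray.shape:
            raise ValidationError("edge map shape does not match the image")

    detections: list[Detection] = []
    run_log: list[tuple[int, list[float]]] = []
    live = edge.copy()
    run_index = 0
    dilate_struct = np.ones(
        (2 * config.mask_dilation + 1, 2 * config.mask_dilation + 1), dtype=bool
    )

    while len(detections) < config.max_detections:
        try:
            edges = edges_to_list(live)
        except TooFewEdgesError:
            if not detections:
                warnings.warn("too few edge pixels; no detection attempted", stacklevel=2)
            break

        accepted = None
        for attempt in range(config.n_restarts):
            # derive an independent, reproducible stream per (master seed, run)
            run_seed = np.random.SeedSequence(
                entropy=(int(config.seed), run_index)
            ).generate_state(1)[0]
            de_config = DEConfig(
                bounds=((0.0, float(edges.count - 1)),) * 5,
                pop_size=config.pop_size,
                scale_factor=config.scale_factor,
                crossover_rate=config.crossover_rate,
                n_generations=config.n_generations,
                seed=int(run_seed),
                stop_below=config.stop_below,
            )
            objective = lambda genes: evaluate_candidate(  # noqa: E731
                Candidate(genes), edges, live, config.limits
            ).value
            best_genes, best_value, history = run_de(objective, de_config)
            run_log.append((run_index, history))
            run_index += 1
            if best_value <= config.accept_threshold:
                ellipse = candidate_to_ellipse(
                    Candidate(best_genes), edges, (height, width), config.limits
                )
                if ellipse is not None:
                    accepted = Detection(ellipse=ellipse, score=float(best_value), run_index=run_index - 1)
                    break
        if accepted is None:
            break

        detections.append(accepted)
        perimeter = mea_rasterize(accepted.ellipse, (width, height))
        hit = np.zeros_like(live)
        hit[perimeter.pixels[:, 1], perimeter.pixels[:, 0]] = True
        if config.mask_dilation > 0:
            hit = ndimage.binary_dilation(hit, structure=dilate_struct)
        live &= ~hit

    detections.sort(key=lambda d: d.score)
    if return_log:
        return detections, run_log
    return detections


_REPORT_COLUMNS = ["x0", "y0", "rmax", "rmin", "theta_deg", "J"]


def write_report(detections, path) -> None:
    """Write detections as CSV or JSON (by extension), one row per detection.

    Values are rounded to six decimals so a read-back compares equal.
    """
    rows = [
        {
            "x0": round(d.ellipse.x0, 6),
            "y0": round(d.ellipse.y0, 6),
            "rmax": round(d.ellipse.rmax, 6),
            "rmin": round(d.ellipse.rmin, 6),
            "theta_deg": round(np.degrees(d.ellipse.theta), 6),
            "J": round(d.score, 6),
        }
        for d in detections
    ]
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")
    else:
        frame = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
        frame.to_csv(path, index=False, float_format="%.6f")


def read_report(path) -> list[Detection]:
    """Read a report written by :func:`write_report` back into detections."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            rows = json.load(fh)
    else:
        rows = pd.read_csv(path).to_dict("records")
    return [
        Detection(
            ellipse=EllipseParams(
                x0=float(r["x0"]),
                y0=float(r["y0"]),
                rmax=float(r["rmax"]),
                rmin=float(r["rmin"]),
                theta=float(np.radians(r["theta_deg"])),
            ),
            score=float(r["J"]),
            run_index=i,
        )
        for i, r in enumerate(rows)
    ]
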