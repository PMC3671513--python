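"""Detection-rate / false-alarm-rate evaluation against ground truth.

DR is the percentage of expert-counted (here: generator ground-truth) cells
correctly detected; FAR is the percentage of spurious detections relative to
the same expert total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError, ValidationError

__all__ = ["MatchResult", "match_detections", "compute_dr_far"]


@dataclass(frozen=True)
class MatchResult:
    """Corpus-level counts; ``detected_correct + missing == expert_total``."""

    detected_correct: int
    missing: int
    false_alarms: int
    expert_total: int

    def __post_init__(self) -> None:
        if min(self.detected_correct, self.missing, self.false_alarms, self.expert_total) < 0:
            raise ValidationError("counts must be non-negative")
        if self.detected_correct + self.missing != self.expert_total:
            raise ValidationError("detected_correct + missing must equal expert_total")

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            detected_correct=self.detected_correct + other.detected_correct,
            missing=self.missing + other.missing,
            false_alarms=self.false_alarms + other.false_alarms,
            expert_total=self.expert_total + other.expert_total,
        )


def match_detections(
    detections,
    truth,
    center_tol: float = 5.0,
    axis_tol: float = 0.25,
) -> MatchResult:
    """Greedy one-to-one matching of detections to ground-truth ellipses.

    Candidate pairs are ranked by ascending center distance; a pair matches
    only if the distance is within ``center_tol`` pixels and both semi-axes
    agree within ``axis_tol`` relative error.  Ties are broken on coordinate
    values so the result does not depend on list order.
    """
    if center_tol <= 0 or axis_tol <= 0:
        raise ValidationError("tolerances must be positive")
    pairs = []
    for ti, t in enumerate(truth):
        for di, d in enumerate(detections):
            dist = float(np.hypot(d.x0 - t.x0, d.y0 - t.y0))
            if dist > center_tol:
                continue
            if abs(d.rmax - t.rmax) / t.rmax > axis_tol:
                continue
            if abs(d.rmin - t.rmin) / t.rmin > axis_tol:
                continue
            pairs.append((dist, t.x0, t.y0, d.x0, d.y0, ti, di))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    correct = 0
    for _, _, _, _, _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        correct += 1
    n_truth = len(list(truth))
    n_det = len(list(detections))
    return MatchResult(
        detected_correct=correct,
        missing=n_truth - correct,
        false_alarms=n_det - correct,
        expert_total=n_truth,
    )


def compute_dr_far(result: MatchResult) -> tuple[float, float]:
    """Detection rate and false-alarm rate as percentages, rounded to 2 d.p.

    ``DR = 100 * detected_correct / expert_total`` and
    ``FAR = 100 * false_alarms / expert_total``.

    Raises
    ------
    UndefinedMetricError
        If ``expert_total`` is zero.
    """
    if result.expert_total == 0:
        raise UndefinedMetricError("expert_total is zero; DR/FAR undefined")
    dr = round(100.0 * result.detected_correct / result.expert_total, 2)
    far = round(100.0 * result.false_alarms / result.expert_total, 2)
    return dr, far
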