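"""Redundancy removal within a single detection set: NMS and Soft-NMS.

Hard NMS is used inside the slide pipeline (collapsing duplicates that arise
when overlapping patches each detect the same object) and doubles as a
baseline ensemble method when applied to pooled multi-model detections.
Soft-NMS is provided as a comparison baseline only: instead of deleting
overlapping detections it decays their confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

from .errors import ConfigError, InvalidInputError
from .geometry import Circle, circle_iou

__all__ = ["SuppressionConfig", "nms", "soft_nms"]


@dataclass(frozen=True)
class SuppressionConfig:
    """Parameters for NMS and Soft-NMS.

    iou_threshold — a detection is suppressed when its circle IoU with an
    already-kept detection *exceeds* this value (hard NMS).
    sigma — Gaussian decay width for Soft-NMS: surviving scores are
    multiplied by exp(−IoU²/σ).
    score_floor — Soft-NMS drops detections whose decayed score falls below
    this value.
    """

    iou_threshold: float = 0.5
    sigma: float = 0.5
    score_floor: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold < 1.0):
            raise ConfigError(f"iou_threshold must be in (0,1), got {self.iou_threshold}")
        if not self.sigma > 0:
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")
        if self.score_floor < 0:
            raise ConfigError(f"score_floor must be >= 0, got {self.score_floor}")


def _sort_key(c: Circle):
    # Deterministic tie-break: score desc, then cx, cy, r ascending, so the
    # result never depends on input permutation.
    return (-c.score, c.cx, c.cy, c.r)


def _require_scores(dets: Sequence[Circle], op: str) -> None:
    for c in dets:
        if c.score is None:
            raise InvalidInputError(f"{op} requires every circle to carry a score")


def nms(dets: Sequence[Circle], cfg: SuppressionConfig | None = None) -> list[Circle]:
    """Greedy non-maximum suppression by descending confidence.

    Walks detections from highest to lowest score, keeping a detection unless
    its IoU with an already-kept one exceeds ``cfg.iou_threshold`` — i.e. for
    each group of mutually redundant detections only the one with the highest
    confidence survives.  Kept circles are returned unmodified, in
    descending-score order.
    """
    cfg = cfg or SuppressionConfig()
    _require_scores(dets, "nms")
    kept: list[Circle] = []
    for cand in sorted(dets, key=_sort_key):
        if all(circle_iou(cand, k) <= cfg.iou_threshold for k in kept):
            kept.append(cand)
    return kept


def soft_nms(dets: Sequence[Circle], cfg: SuppressionConfig | None = None) -> list[Circle]:
    """Soft-NMS with Gaussian score decay applied to circle IoU.

    Iteratively pops the highest-scored remaining detection as kept, then
    multiplies every other remaining score by exp(−IoU²/σ) against the kept
    circle.  Detections whose score drops below ``cfg.score_floor`` are
    discarded; geometry is never modified.
    """
    cfg = cfg or SuppressionConfig()
    _require_scores(dets, "soft_nms")
    remaining = list(dets)
    kept: list[Circle] = []
    while remaining:
        remaining.sort(key=_sort_key)
        top = remaining.pop(0)
        kept.append(top)
        rescored: list[Circle] = []
        for c in remaining:
            iou = circle_iou(top, c)
            new_score = c.score * math.exp(-(iou * iou) / cfg.sigma)
            if new_score >= cfg.score_floor:
                rescored.append(c.with_score(new_score))
        remaining = rescored
    return kept
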