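"""Exact circle geometry: areas, the circle-IoU metric, and pairwise IoU matrices.

Detections are represented as circles (center + radius) rather than bounding
boxes, so every overlap computation in the pipeline — suppression, fusion,
evaluation — reduces to the analytic intersection-over-union of two discs.
Coordinates follow the image convention: 0-based continuous pixels, x growing
rightward, y growing downward.  All geometry here is frame-agnostic; whether a
circle lives in patch-local or slide-global coordinates is bookkeeping kept by
the collections that carry them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidGeometryError

__all__ = ["Circle", "circle_area", "circle_iou", "pairwise_iou"]


@dataclass(frozen=True)
class Circle:
    """A detected or ground-truth circular object.

    Parameters
    ----------
    cx, cy : float
        Center, in continuous 0-based pixels (x rightward, y downward).
    r : float
        Radius in pixels, strictly positive.
    score : float or None
        Detection confidence in [0, 1]; ``None`` for ground-truth objects.
    model_id : str or None
        Provenance label of the detector that produced this circle.
    category : str
        Free-text class label; the pipeline's target class by default.
    """

    cx: float
    cy: float
    r: float
    score: float | None = None
    model_id: str | None = None
    category: str = "glomerulus"

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise InvalidGeometryError(f"circle radius must be > 0, got {self.r}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise InvalidGeometryError(f"score must lie in [0, 1], got {self.score}")

    def translated(self, dx: float, dy: float) -> "Circle":
        """Return a copy shifted by (dx, dy); radius, score, provenance kept."""
        return replace(self, cx=self.cx + dx, cy=self.cy + dy)

    def with_score(self, score: float) -> "Circle":
        return replace(self, score=score)


def circle_area(c: Circle) -> float:
    """Area of a circle in px² (πr²)."""
    if not c.r > 0:
        raise InvalidGeometryError(f"circle radius must be > 0, got {c.r}")
    return math.pi * c.r * c.r


def _lens_area(d: float, ra: float, rb: float) -> float:
    """Area of intersection of two discs with center distance d (general case)."""
    # Clamp acos arguments: tangency/containment boundaries can drift past ±1
    # by a few ulps.
    arg_a = (d * d + ra * ra - rb * rb) / (2.0 * d * ra)
    arg_b = (d * d + rb * rb - ra * ra) / (2.0 * d * rb)
    arg_a = min(1.0, max(-1.0, arg_a))
    arg_b = min(1.0, max(-1.0, arg_b))
    term = (-d + ra + rb) * (d + ra - rb) * (d - ra + rb) * (d + ra + rb)
    term = max(term, 0.0)
    return (
        ra * ra * math.acos(arg_a)
        + rb * rb * math.acos(arg_b)
        - 0.5 * math.sqrt(term)
    )


def circle_iou(a: Circle, b: Circle) -> float:
    """Intersection-over-union of two circles.

    The ratio of the overlap area to the combined (union) area of the two
    discs.  Symmetric, invariant under rigid motions, 1.0 for identical
    circles, and exactly 0.0 once the circles are tangent or disjoint.
    """
    if not (a.r > 0 and b.r > 0):
        raise InvalidGeometryError("circle_iou requires strictly positive radii")
    # Canonical operand order makes the result exactly symmetric despite
    # floating-point summation order in the lens formula.
    if (b.r, b.cx, b.cy) < (a.r, a.cx, a.cy):
        a, b = b, a
    d = math.hypot(a.cx - b.cx, a.cy - b.cy)
    if d == 0.0 and a.r == b.r:
        return 1.0
    ra, rb = a.r, b.r
    if d >= ra + rb:
        return 0.0
    area_a = math.pi * ra * ra
    area_b = math.pi * rb * rb
    if d <= abs(ra - rb):
        # One circle contains the other: IoU is the area ratio.
        return min(area_a, area_b) / max(area_a, area_b)
    inter = _lens_area(d, ra, rb)
    union = area_a + area_b - inter
    return inter / union


def pairwise_iou(A: Sequence[Circle] | Iterable[Circle],
                 B: Sequence[Circle] | Iterable[Circle]) -> np.ndarray:
    """|A|×|B| matrix of circle IoUs, vectorised; no thresholding.

    Empty inputs yield an empty matrix of the appropriate shape.
    """
    A = list(A)
    B = list(B)
    if not A or not B:
        return np.zeros((len(A), len(B)), dtype=float)
    ax = np.array([c.cx for c in A])[:, None]
    ay = np.array([c.cy for c in A])[:, None]
    ar = np.array([c.r for c in A])[:, None]
    bx = np.array([c.cx for c in B])[None, :]
    by = np.array([c.cy for c in B])[None, :]
    br = np.array([c.r for c in B])[None, :]
    if np.any(ar <= 0) or np.any(br <= 0):
        raise InvalidGeometryError("pairwise_iou requires strictly positive radii")

    d = np.hypot(ax - bx, ay - by)
    area_a = np.pi * ar * ar
    area_b = np.pi * br * br

    out = np.zeros(d.shape, dtype=float)

    contained = d <= np.abs(ar - br)
    np.copyto(out, np.minimum(area_a, area_b) / np.maximum(area_a, area_b),
              where=contained)

    partial = (~contained) & (d < ar + br)
    if np.any(partial):
        with np.errstate(divide="ignore", invalid="ignore"):
            arg_a = (d * d + ar * ar - br * br) / (2.0 * d * ar)
            arg_b = (d * d + br * br - ar * ar) / (2.0 * d * br)
        arg_a = np.clip(arg_a, -1.0, 1.0)
        arg_b = np.clip(arg_b, -1.0, 1.0)
        term = (-d + ar + br) * (d + ar - br) * (d - ar + br) * (d + ar + br)
        term = np.maximum(term, 0.0)
        inter = (ar * ar * np.arccos(arg_a)
                 + br * br * np.arccos(arg_b)
                 - 0.5 * np.sqrt(term))
        iou = inter / (area_a + area_b - inter)
        np.copyto(out, iou, where=partial)

    identical = (d == 0.0) & (ar == br)
    out[identical] = 1.0
    return out
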