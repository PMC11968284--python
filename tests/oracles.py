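"""Independent reference implementations used as test oracles.

Each oracle follows its operation's definition literally (loops, no shared
code with the package internals) so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

from circlefuse.geometry import Circle, circle_iou


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is normally available
    _njit = None


def _mc_counts_numpy(uv, x_lo, x_span, y_lo, y_span, ax, ay, ra2, bx, by, rb2):
    x = x_lo + uv[:, 0].astype(np.float64) * x_span
    y = y_lo + uv[:, 1].astype(np.float64) * y_span
    in_a = (x - ax) ** 2 + (y - ay) ** 2 <= ra2
    in_b = (x - bx) ** 2 + (y - by) ** 2 <= rb2
    return int(np.count_nonzero(in_a & in_b)), int(np.count_nonzero(in_a | in_b))


def _mc_counts_loop(uv, x_lo, x_span, y_lo, y_span, ax, ay, ra2, bx, by, rb2):
    n_int = 0
    n_uni = 0
    for i in range(uv.shape[0]):
        x = x_lo + np.float64(uv[i, 0]) * x_span
        y = y_lo + np.float64(uv[i, 1]) * y_span
        da = (x - ax) ** 2 + (y - ay) ** 2 <= ra2
        db = (x - bx) ** 2 + (y - by) ** 2 <= rb2
        if da and db:
            n_int += 1
        if da or db:
            n_uni += 1
    return n_int, n_uni


_mc_counts = _njit(cache=False)(_mc_counts_loop) if _njit else _mc_counts_numpy


def mc_iou(a: Circle, b: Circle, uv: np.ndarray) -> float:
    """Monte-Carlo circle IoU: hit counting over the union's bounding box.

    ``uv`` is an (n, 2) array of uniforms in [0,1); the ratio estimator
    n_intersection / n_union cancels the box area.  Disjoint circles give
    exactly 0 (no sample can land in both).
    """
    x_lo = min(a.cx - a.r, b.cx - b.r)
    x_hi = max(a.cx + a.r, b.cx + b.r)
    y_lo = min(a.cy - a.r, b.cy - b.r)
    y_hi = max(a.cy + a.r, b.cy + b.r)
    n_int, n_uni = _mc_counts(uv, x_lo, x_hi - x_lo, y_lo, y_hi - y_lo,
                              a.cx, a.cy, a.r * a.r, b.cx, b.cy, b.r * b.r)
    if n_uni == 0:
        return 0.0
    return n_int / n_uni


def brute_nms(dets: list[Circle], iou_threshold: float) -> list[Circle]:
    """Literal greedy NMS: sort, then keep unless overlapping a kept circle."""
    order = sorted(dets, key=lambda c: (-c.score, c.cx, c.cy, c.r))
    kept: list[Circle] = []
    for c in order:
        suppressed = False
        for k in kept:
            if circle_iou(c, k) > iou_threshold:
                suppressed = True
                break
        if not suppressed:
            kept.append(c)
    return kept


def brute_soft_nms(dets: list[Circle], sigma: float,
                   score_floor: float) -> list[Circle]:
    """Literal Soft-NMS loop: pop max, Gaussian-decay the rest, drop low."""
    pool = list(dets)
    kept: list[Circle] = []
    while pool:
        pool.sort(key=lambda c: (-c.score, c.cx, c.cy, c.r))
        top = pool.pop(0)
        kept.append(top)
        nxt = []
        for c in pool:
            iou = circle_iou(top, c)
            s = c.score * math.exp(-(iou * iou) / sigma)
            if s >= score_floor:
                nxt.append(c.with_score(s))
        pool = nxt
    return kept


def brute_wcf(per_model: dict[str, list[Circle]], t_iou: float, t_count: int,
              t_score: float, drop_below_count: bool = True):
    """Literal step-by-step weighted circle fusion reference.

    Returns a list of (members, fused (cx, cy, r), fused_score, model_count)
    for surviving clusters, sorted by fused score descending.
    """
    pooled = []
    for mid, dets in per_model.items():
        for c in dets:
            pooled.append(c if c.model_id else
                          Circle(c.cx, c.cy, c.r, score=c.score, model_id=mid))
    pooled.sort(key=lambda c: (-c.score, c.cx, c.cy, c.r))

    clusters: list[list[Circle]] = []

    def fuse_geom(members):
        w = [m.score for m in members]
        ws = sum(w)
        cx = sum(wi * m.cx for wi, m in zip(w, members)) / ws
        cy = sum(wi * m.cy for wi, m in zip(w, members)) / ws
        r = sum(wi * m.r for wi, m in zip(w, members)) / ws
        return cx, cy, r

    for det in pooled:
        for members in clusters:
            cx, cy, r = fuse_geom(members)
            if circle_iou(det, Circle(cx, cy, r)) > t_iou:
                members.append(det)
                break
        else:
            clusters.append([det])

    out = []
    for members in clusters:
        count = len({m.model_id for m in members})
        score = sum(m.score for m in members) / len(members)
        if drop_below_count and count < t_count:
            continue
        if score < t_score:
            continue
        out.append((members, fuse_geom(members), score, count))
    out.sort(key=lambda t: (-t[2], t[1][0], t[1][1], t[1][2]))
    return out


def brute_match(dets: list[Circle], gts: list[Circle], thr: float):
    """Literal greedy matching: score order, best unmatched GT with IoU >= thr."""
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i].score, dets[i].cx, dets[i].cy, dets[i].r))
    taken = [False] * len(gts)
    tp = []
    for i in order:
        best_j, best_iou = -1, -1.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            iou = circle_iou(dets[i], g)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= thr:
            taken[best_j] = True
            tp.append(True)
        else:
            tp.append(False)
    return order, tp, taken


def ap_101(flags: list[bool], n_gt: int) -> float:
    """Direct 101-point AP summation from the definition."""
    tp = 0
    fp = 0
    points = []
    for f in flags:
        tp += f
        fp += not f
        points.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for k in range(101):
        r = k / 100.0
        best = max((p for rr, p in points if rr >= r - 1e-12), default=0.0)
        total += best
    return total / 101.0


def random_circles(rng: np.random.Generator, n: int, extent: float = 1000.0,
                   r_lo: float = 5.0, r_hi: float = 60.0,
                   scored: bool = True, model_id: str | None = None) -> list[Circle]:
    """Uniform random scored circles for oracle comparisons."""
    out = []
    for _ in range(n):
        out.append(Circle(cx=float(rng.uniform(0, extent)),
                          cy=float(rng.uniform(0, extent)),
                          r=float(rng.uniform(r_lo, r_hi)),
                          score=float(rng.uniform(0.01, 1.0)) if scored else None,
                          model_id=model_id))
    return out
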