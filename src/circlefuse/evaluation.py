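"""Detection scoring with circle IoU: greedy matching, average precision,
mAP over an IoU-threshold grid, and average recall.

The protocol follows the standard COCO convention, with circle IoU in place
of box IoU: detections are matched greedily in descending score order, each
to the highest-IoU still-unmatched ground-truth circle at or above the
threshold; AP is the (by default 101-point interpolated) area under the
precision-recall curve; mAP averages AP over thresholds 0.50–0.95 in steps
of 0.05; average recall is the mean over that grid of the recalled fraction
of ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geometry import Circle, pairwise_iou

__all__ = [
    "EvalConfig", "EvalResult", "MatchResult",
    "match_detections", "average_precision", "evaluate", "evaluate_dataset",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class EvalConfig:
    """Thresholds and conventions for evaluation.

    iou_thresholds — strictly increasing grid in (0,1); default 0.50–0.95
    in steps of 0.05.
    max_dets — cap on scored detections per slide (top-scored kept).
    interpolation — "101-point" (COCO) or "all-point" (exact PR-curve area,
    handy for hand-checkable examples).
    """

    iou_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    max_dets: int = 500
    interpolation: Literal["101-point", "all-point"] = "101-point"

    def __post_init__(self) -> None:
        t = self.iou_thresholds
        if not t or any(not (0 < x < 1) for x in t) or any(
                b <= a for a, b in zip(t, t[1:])):
            raise ConfigError("iou_thresholds must be strictly increasing within (0,1)")
        if self.max_dets < 1:
            raise ConfigError("max_dets must be >= 1")


@dataclass(frozen=True)
class EvalResult:
    """AP per IoU threshold plus the usual aggregates.

    ``defined`` is False when there is neither ground truth nor detections,
    in which case every metric field is None.
    """

    ap_by_threshold: dict[float, float | None]
    map_50: float | None
    map_75: float | None
    map_50_95: float | None
    average_recall: float | None
    defined: bool = True


@dataclass(frozen=True)
class MatchResult:
    """Greedy matching outcome at one IoU threshold.

    ``tp`` flags are aligned with ``order`` — detection indices sorted by
    descending score (deterministic tie-break).
    """

    order: tuple[int, ...]
    tp: tuple[bool, ...]
    gt_matched: tuple[bool, ...]


def _det_order(dets: Sequence[Circle]) -> list[int]:
    return sorted(range(len(dets)),
                  key=lambda i: (-dets[i].score, dets[i].cx, dets[i].cy, dets[i].r))


def match_detections(dets: Sequence[Circle], gts: Sequence[Circle],
                     iou_thr: float) -> MatchResult:
    """Greedy score-ordered matching: each detection claims the highest-IoU
    unmatched ground truth with IoU ≥ ``iou_thr`` (TP), else it is an FP;
    each ground truth is matched at most once."""
    order = _det_order(dets)
    iou = pairwise_iou(dets, gts)
    gt_taken = np.zeros(len(gts), dtype=bool)
    tp: list[bool] = []
    for i in order:
        row = iou[i].copy() if len(gts) else np.empty(0)
        if len(gts):
            row[gt_taken] = -1.0
            j = int(np.argmax(row)) if row.size else -1
            if row.size and row[j] >= iou_thr:
                gt_taken[j] = True
                tp.append(True)
                continue
        tp.append(False)
    return MatchResult(order=tuple(order), tp=tuple(tp),
                       gt_matched=tuple(bool(x) for x in gt_taken))


def average_precision(flags: Sequence[bool], n_gt: int,
                      interpolation: str = "101-point") -> float | None:
    """AP from ordered TP/FP flags.

    ``flags`` must be in descending-score order.  With no ground truth and
    no detections the metric is undefined and None is returned; with
    detections but no ground truth every detection is an FP and AP is 0.
    """
    flags = np.asarray(flags, dtype=bool)
    if n_gt == 0:
        return None if flags.size == 0 else 0.0
    if flags.size == 0:
        return 0.0
    cum_tp = np.cumsum(flags)
    cum_fp = np.cumsum(~flags)
    precision = cum_tp / (cum_tp + cum_fp)
    recall = cum_tp / n_gt
    # Precision envelope: best precision achievable at recall >= r.
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "101-point":
        grid = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(recall, grid, side="left")
        vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(vals.mean())
    if interpolation == "all-point":
        r_prev = np.concatenate(([0.0], recall[:-1]))
        return float(np.sum((recall - r_prev) * env))
    raise ConfigError(f"unknown interpolation {interpolation!r}")


def evaluate(dets: Sequence[Circle], gts: Sequence[Circle],
             cfg: EvalConfig | None = None) -> EvalResult:
    """Score one slide's detections against its ground truth.

    Runs matching and AP at every configured IoU threshold; average recall
    is the mean over thresholds of the recalled ground-truth fraction, using
    at most ``max_dets`` top-scored detections throughout.
    """
    cfg = cfg or EvalConfig()
    if not dets and not gts:
        return EvalResult(ap_by_threshold={t: None for t in cfg.iou_thresholds},
                          map_50=None, map_75=None, map_50_95=None,
                          average_recall=None, defined=False)
    order = _det_order(dets)[: cfg.max_dets]
    capped = [dets[i] for i in order]

    ap_by_thr: dict[float, float | None] = {}
    recalls: list[float] = []
    for thr in cfg.iou_thresholds:
        m = match_detections(capped, gts, thr)
        ap_by_thr[thr] = average_precision(m.tp, len(gts), cfg.interpolation)
        if len(gts):
            recalls.append(sum(m.gt_matched) / len(gts))
        else:
            recalls.append(0.0)

    vals = [v for v in ap_by_thr.values() if v is not None]
    map_50_95 = float(np.mean(vals)) if vals else None

    def _at(thr: float) -> float | None:
        for t, v in ap_by_thr.items():
            if abs(t - thr) < 1e-9:
                return v
        return None

    return EvalResult(ap_by_threshold=ap_by_thr, map_50=_at(0.5), map_75=_at(0.75),
                      map_50_95=map_50_95,
                      average_recall=float(np.mean(recalls)) if recalls else None,
                      defined=True)


def evaluate_dataset(dets_by_slide: Mapping[str, Sequence[Circle]],
                     gts_by_slide: Mapping[str, Sequence[Circle]],
                     cfg: EvalConfig | None = None,
                     pooled: bool = False) -> tuple[dict[str, EvalResult], EvalResult]:
    """Evaluate several slides; aggregate by per-slide averaging (default).

    Per-slide averaging computes an EvalResult per slide and averages the
    metrics over slides with at least one ground-truth object.  With
    ``pooled`` the whole dataset is scored as one instance instead: slides
    are laid side by side with disjoint offsets (so circles from different
    slides can never match) and a single PR curve is built from the pooled
    ranking.
    """
    cfg = cfg or EvalConfig()
    slides = sorted(set(gts_by_slide) | set(dets_by_slide))
    per_slide = {s: evaluate(list(dets_by_slide.get(s, [])),
                             list(gts_by_slide.get(s, [])), cfg)
                 for s in slides}
    if pooled:
        # Concatenate with a frame offset so circles from different slides
        # can never overlap, then evaluate once.
        all_dets: list[Circle] = []
        all_gts: list[Circle] = []
        offset = 0.0
        for s in slides:
            gts = list(gts_by_slide.get(s, []))
            dts = list(dets_by_slide.get(s, []))
            span = max([c.cx + c.r for c in gts + dts], default=0.0) + 10.0
            all_gts.extend(c.translated(offset, 0.0) for c in gts)
            all_dets.extend(c.translated(offset, 0.0) for c in dts)
            offset += span
        agg = evaluate(all_dets, all_gts, cfg)
        return per_slide, agg

    scored = [r for s, r in per_slide.items()
              if len(gts_by_slide.get(s, [])) > 0 and r.defined]
    if not scored:
        agg = EvalResult(ap_by_threshold={t: None for t in cfg.iou_thresholds},
                         map_50=None, map_75=None, map_50_95=None,
                         average_recall=None, defined=False)
        return per_slide, agg

    def _mean(key) -> float | None:
        vals = [key(r) for r in scored if key(r) is not None]
        return float(np.mean(vals)) if vals else None

    ap_mean = {t: _mean(lambda r, t=t: r.ap_by_threshold.get(t))
               for t in cfg.iou_thresholds}
    agg = EvalResult(ap_by_threshold=ap_mean,
                     map_50=_mean(lambda r: r.map_50),
                     map_75=_mean(lambda r: r.map_75),
                     map_50_95=_mean(lambda r: r.map_50_95),
                     average_recall=_mean(lambda r: r.average_recall),
                     defined=True)
    return per_slide, agg


def report_frame(per_slide: Mapping[str, EvalResult],
                 aggregate: EvalResult,
                 cfg: EvalConfig | None = None) -> pd.DataFrame:
    """Flat report: one row per slide plus an aggregate row."""
    cfg = cfg or EvalConfig()
    rows = []
    for name, res in list(per_slide.items()) + [("aggregate", aggregate)]:
        row: dict[str, object] = {"slide": name}
        for t in cfg.iou_thresholds:
            row[f"ap@{t:.2f}"] = res.ap_by_threshold.get(t)
        row["map_50"] = res.map_50
        row["map_75"] = res.map_75
        row["map_50_95"] = res.map_50_95
        row["average_recall"] = res.average_recall
        rows.append(row)
    return pd.DataFrame(rows)
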