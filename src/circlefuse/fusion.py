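"""Weighted circle fusion (WCF): consensus ensembling of circle detections.

Detections from several independently trained models are pooled, clustered by
circle IoU, and each cluster is merged into a single circle whose geometry is
the confidence-weighted average of its members and whose confidence is the
arithmetic mean of member scores.  Two filters then mirror how the method is
deployed: a *consensus count* threshold (a fused detection must be supported
by at least ``t_count`` distinct models, default 2) and a *fused confidence*
threshold (default 0.9).  Detections supported by fewer models are far more
likely to be false positives, which is also why downstream visualisation
colour-codes fused circles by their supporting-model count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .errors import ConfigError, InvalidInputError
from .geometry import Circle, circle_iou

__all__ = ["FusionConfig", "FusedCircle", "wcf", "categorize_by_count"]


@dataclass(frozen=True)
class FusionConfig:
    """Thresholds and conventions for weighted circle fusion.

    t_iou — clustering threshold: a detection joins the first cluster whose
    current fused circle overlaps it with IoU > t_iou.
    t_count — minimum number of distinct supporting models for a fused
    detection to be kept (consensus filter), default 2.
    t_score — minimum fused (averaged) confidence, default 0.9.
    drop_below_count — when off, sub-consensus clusters are returned too so
    they can be colour-coded for review instead of deleted.
    weighting — "score": member geometry averaged with confidence weights;
    "uniform": plain mean.
    score_mode — fused confidence as plain mean (default) or weighted mean.
    """

    t_iou: float = 0.5
    t_count: int = 2
    t_score: float = 0.9
    drop_below_count: bool = True
    weighting: Literal["score", "uniform"] = "score"
    score_mode: Literal["mean", "weighted"] = "mean"

    def __post_init__(self) -> None:
        if not (0.0 < self.t_iou < 1.0):
            raise ConfigError(f"t_iou must be in (0,1), got {self.t_iou}")
        if self.t_count < 1:
            raise ConfigError(f"t_count must be >= 1, got {self.t_count}")
        if not (0.0 <= self.t_score <= 1.0):
            raise ConfigError(f"t_score must be in [0,1], got {self.t_score}")
        if self.weighting not in ("score", "uniform"):
            raise ConfigError(f"unknown weighting {self.weighting!r}")
        if self.score_mode not in ("mean", "weighted"):
            raise ConfigError(f"unknown score_mode {self.score_mode!r}")


@dataclass(frozen=True)
class FusedCircle:
    """One WCF output: merged geometry plus its provenance.

    ``model_count`` counts *distinct* model_ids among the members — the
    quantity the consensus filter and the colour-coded review workflow use.
    """

    circle: Circle
    fused_score: float
    members: tuple[Circle, ...] = ()
    model_count: int = 1

    @property
    def cx(self) -> float:
        return self.circle.cx

    @property
    def cy(self) -> float:
        return self.circle.cy

    @property
    def r(self) -> float:
        return self.circle.r


class _Cluster:
    __slots__ = ("members", "fused")

    def __init__(self, first: Circle, cfg: FusionConfig):
        self.members: list[Circle] = [first]
        self.fused: Circle = first
        self._refit(cfg)

    def add(self, c: Circle, cfg: FusionConfig) -> None:
        self.members.append(c)
        self._refit(cfg)

    def _refit(self, cfg: FusionConfig) -> None:
        if cfg.weighting == "score":
            weights = [m.score for m in self.members]
        else:
            weights = [1.0] * len(self.members)
        wsum = sum(weights)
        if wsum <= 0:
            weights = [1.0] * len(self.members)
            wsum = float(len(self.members))
        cx = sum(w * m.cx for w, m in zip(weights, self.members)) / wsum
        cy = sum(w * m.cy for w, m in zip(weights, self.members)) / wsum
        r = sum(w * m.r for w, m in zip(weights, self.members)) / wsum
        self.fused = Circle(cx=cx, cy=cy, r=r, score=self.fused_score(cfg))

    def fused_score(self, cfg: FusionConfig) -> float:
        scores = [m.score for m in self.members]
        if cfg.score_mode == "weighted":
            wsum = sum(scores)
            if wsum > 0:
                return sum(s * s for s in scores) / wsum
        return sum(scores) / len(scores)

    def model_count(self) -> int:
        return len({m.model_id for m in self.members})


def _pool_sort_key(c: Circle):
    return (-c.score, c.cx, c.cy, c.r)


def wcf(per_model_dets: Mapping[str, Sequence[Circle]],
        cfg: FusionConfig | None = None) -> list[FusedCircle]:
    """Fuse per-model detection sets into consensus circles.

    Expects each model's list to be internally deduplicated already (NMS is
    applied upstream in the pipeline) and all circles to share one global
    frame.  Detections are processed in descending score order; each is
    assigned to the first existing cluster whose *current fused circle*
    overlaps it with IoU > ``t_iou``, else it opens a new cluster.  Cluster
    geometry is re-averaged as members join.  Clusters failing the consensus
    count or fused-score thresholds are discarded; survivors are returned
    sorted by fused score, descending.
    """
    cfg = cfg or FusionConfig()
    if not per_model_dets:
        raise InvalidInputError("wcf requires a non-empty model -> detections mapping")
    pooled: list[Circle] = []
    for model_id, dets in per_model_dets.items():
        for c in dets:
            if c.score is None:
                raise InvalidInputError("wcf requires every circle to carry a score")
            if c.model_id is None:
                c = Circle(c.cx, c.cy, c.r, score=c.score, model_id=model_id,
                           category=c.category)
            pooled.append(c)

    clusters: list[_Cluster] = []
    for det in sorted(pooled, key=_pool_sort_key):
        for cl in clusters:
            if circle_iou(det, cl.fused) > cfg.t_iou:
                cl.add(det, cfg)
                break
        else:
            clusters.append(_Cluster(det, cfg))

    out: list[FusedCircle] = []
    for cl in clusters:
        count = cl.model_count()
        score = cl.fused_score(cfg)
        if cfg.drop_below_count and count < cfg.t_count:
            continue
        if score < cfg.t_score:
            continue
        fused_geom = Circle(cl.fused.cx, cl.fused.cy, cl.fused.r, score=score)
        out.append(FusedCircle(circle=fused_geom, fused_score=score,
                               members=tuple(cl.members), model_count=count))
    out.sort(key=lambda f: (-f.fused_score, f.cx, f.cy, f.r))
    return out


def categorize_by_count(fused: Sequence[FusedCircle]) -> dict[str, list[FusedCircle]]:
    """Partition fused circles into named groups "fused_k" by supporting-model count.

    Mirrors the review workflow where circles supported by fewer models are
    flagged for closer human inspection.
    """
    groups: dict[str, list[FusedCircle]] = {}
    for f in fused:
        groups.setdefault(f"fused_{f.model_count}", []).append(f)
    return groups
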