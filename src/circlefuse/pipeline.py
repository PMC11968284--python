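"""Whole-slide orchestration: half-overlap tiling, per-patch detection,
local→global mapping, per-model cross-patch deduplication, then fusion.

A gigapixel slide is tiled into square patches that overlap by half their
area, so an object sitting on a patch boundary is fully contained in at least
one neighbouring patch and is never missed.  Each detector (one per ensemble
model) runs on every patch in patch-local coordinates; detections are
translated back into the slide frame, duplicates from overlapping patches are
collapsed with hard NMS per model, and the per-model sets are fused with
weighted circle fusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

from .errors import ConfigError
from .fusion import FusedCircle, FusionConfig, wcf
from .geometry import Circle
from .suppression import SuppressionConfig, nms

__all__ = [
    "SlideMeta", "PatchSpec", "Detector", "PipelineReport",
    "make_tiles", "to_global", "run_pipeline",
]

logger = logging.getLogger(__name__)

DEFAULT_PATCH = 512
DEFAULT_STRIDE = 256


@dataclass(frozen=True)
class SlideMeta:
    """Slide dimensions and identifier; the global pixel frame."""

    width: int
    height: int
    name: str = "slide"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("slide width and height must be positive")


@dataclass(frozen=True)
class PatchSpec:
    """A half-open patch window [x0, x0+size) × [y0, y0+size) in the slide frame."""

    x0: int
    y0: int
    size: int


@runtime_checkable
class Detector(Protocol):
    """A per-patch detection unit: returns patch-local scored circles.

    Implementations carry their own ``model_id`` and, for synthetic
    detectors, a reference to the simulated truth; real implementations
    would read pixel data for the patch window.
    """

    model_id: str

    def __call__(self, patch: PatchSpec) -> Sequence[Circle]: ...


def _axis_origins(extent: int, patch: int, stride: int) -> list[int]:
    origins = []
    k = 0
    while k * stride + patch <= extent:
        origins.append(k * stride)
        k += 1
    # Anchor a final patch at the far edge when the regular grid stops short.
    if origins[-1] + patch < extent:
        origins.append(extent - patch)
    return origins


def make_tiles(slide: SlideMeta, patch: int = DEFAULT_PATCH,
               stride: int | None = None) -> list[PatchSpec]:
    """Half-overlap tiling of a slide into square patches.

    Per axis, patch origins step by ``stride`` (default patch/2) while the
    patch still fits; when the last regular patch stops short of the edge, a
    final patch is anchored flush with the edge so every pixel is covered.
    The grid is the cross product of the two axis origin lists.
    """
    if stride is None:
        stride = patch // 2
    if not (0 < stride <= patch):
        raise ConfigError(f"stride must satisfy 0 < stride <= patch, got {stride}")
    if slide.width < patch or slide.height < patch:
        raise ConfigError(
            f"slide {slide.width}x{slide.height} smaller than patch {patch}; "
            "pad the slide or choose a smaller patch")
    xs = _axis_origins(slide.width, patch, stride)
    ys = _axis_origins(slide.height, patch, stride)
    return [PatchSpec(x0=x, y0=y, size=patch) for y in ys for x in xs]


def to_global(local: Circle, patch: PatchSpec) -> Circle:
    """Map a patch-local circle into the slide frame (pure translation).

    A center outside the patch window is kept with a warning — detections
    hugging a patch edge are legitimate.
    """
    if not (0 <= local.cx < patch.size and 0 <= local.cy < patch.size):
        logger.warning(
            "detection center (%.1f, %.1f) outside patch window of size %d; kept",
            local.cx, local.cy, patch.size)
    return local.translated(patch.x0, patch.y0)


@dataclass
class PipelineReport:
    """Partial-result bookkeeping for a pipeline run."""

    n_patches: int = 0
    n_models: int = 0
    raw_per_model: dict[str, int] = field(default_factory=dict)
    deduped_per_model: dict[str, int] = field(default_factory=dict)
    skipped: list[tuple[str, PatchSpec]] = field(default_factory=list)
    n_fused: int = 0


def run_pipeline(slide: SlideMeta,
                 detectors: Sequence[Detector],
                 sup_cfg: SuppressionConfig | None = None,
                 fusion_cfg: FusionConfig | None = None,
                 patch: int = DEFAULT_PATCH,
                 stride: int | None = None,
                 report: PipelineReport | None = None) -> list[FusedCircle]:
    """Tile → detect → translate → per-model NMS → weighted circle fusion.

    Runs every detector over every patch, maps detections to the slide
    frame, removes the near-identical duplicates that overlapping patches
    produce (hard NMS within each model's pooled detections), then fuses
    across models.  A detector raising on a patch is logged and that patch
    is skipped for that model only; the run completes with partial results,
    summarised in ``report`` if one is passed in.
    """
    if not detectors:
        raise ConfigError("run_pipeline requires at least one detector")
    sup_cfg = sup_cfg or SuppressionConfig()
    fusion_cfg = fusion_cfg or FusionConfig()
    tiles = make_tiles(slide, patch=patch, stride=stride)

    per_model: dict[str, list[Circle]] = {}
    skipped: list[tuple[str, PatchSpec]] = []
    for det in detectors:
        pooled: list[Circle] = []
        for tile in tiles:
            try:
                local_dets = det(tile)
            except Exception:
                logger.exception("detector %s failed on patch (%d,%d); skipping",
                                 det.model_id, tile.x0, tile.y0)
                skipped.append((det.model_id, tile))
                continue
            for c in local_dets:
                g = to_global(c, tile)
                if g.model_id is None:
                    g = Circle(g.cx, g.cy, g.r, score=g.score,
                               model_id=det.model_id, category=g.category)
                pooled.append(g)
        per_model[det.model_id] = pooled

    deduped = {mid: nms(dets, sup_cfg) for mid, dets in per_model.items()}
    fused = wcf(deduped, fusion_cfg)

    if skipped:
        logger.warning("pipeline finished with %d skipped (model, patch) pairs",
                       len(skipped))
    if report is not None:
        report.n_patches = len(tiles)
        report.n_models = len(detectors)
        report.raw_per_model = {m: len(v) for m, v in per_model.items()}
        report.deduped_per_model = {m: len(v) for m, v in deduped.items()}
        report.skipped = skipped
        report.n_fused = len(fused)
    return fused
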