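"""Synthetic benchmark: virtual slides with ground-truth circles and an
ensemble of parameterised noisy detectors.

The generator emulates the deployment setting of the real pipeline — a
whole-slide image containing on the order of a hundred roughly circular,
non-overlapping objects (glomeruli), scanned by an ensemble of five
independently trained detectors — without any pixels, weights or downloads.
Each simulated detector misses a fraction of objects, jitters the location
and radius of the ones it finds, assigns confidence scores from a Beta
distribution skewed high for true detections, and sprinkles false positives
at a fixed rate per megapixel with a low-skewed (but heavy-upper-tailed)
confidence distribution.  Because each model's false positives are
independent while true detections are shared, consensus filtering separates
them — the property the fusion method exploits.

Per-model randomness comes from independent seed streams derived from
(seed, model_index), so adding a model never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, PackingError
from .geometry import Circle
from .pipeline import PatchSpec
from .qupath import (circles_from_frame, frame_from_circles,
                     read_detections_csv, write_detections_csv)

__all__ = [
    "SimConfig", "Benchmark", "PrecomputedDetector",
    "generate_ground_truth", "simulate_detector", "make_ensemble_benchmark",
    "write_bundle", "read_bundle",
]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the virtual slide and detector ensemble.

    Defaults describe one virtual slide of a plausible evaluation set:
    a 4096×4096 px region holding 130 non-overlapping circular objects with
    radii 40–120 px (well under half a 512 px patch, so every object fits in
    a patch), scanned by five detectors that each find 90 % of the objects,
    localise them with 3 px isotropic center jitter and 5 % relative radius
    jitter, and emit 2 false positives per megapixel.  True-detection
    confidences follow Beta(40, 2) (mean ≈ 0.95); false-positive
    confidences follow Beta(0.5, 1.0) — a decreasing density (mean 1/3)
    whose upper tail models the occasional high-confidence hard negative,
    making score-only filtering insufficient, as with real detectors.
    """

    width: int = 4096
    height: int = 4096
    n_gt: int = 130
    radius_range: tuple[float, float] = (40.0, 120.0)
    min_separation: float = 260.0
    n_models: int = 5
    p_detect: float = 0.9
    center_jitter_sd: float = 3.0
    radius_jitter_sd: float = 0.05
    fp_per_megapixel: float = 2.0
    tp_score_params: tuple[float, float] | None = (40.0, 2.0)
    fp_score_params: tuple[float, float] = (0.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_detect <= 1.0):
            raise ConfigError(f"p_detect must be in [0,1], got {self.p_detect}")
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise ConfigError(f"invalid radius_range {self.radius_range}")
        if self.n_gt < 0 or self.n_models < 1:
            raise ConfigError("n_gt must be >= 0 and n_models >= 1")
        if self.center_jitter_sd < 0 or self.radius_jitter_sd < 0:
            raise ConfigError("jitter standard deviations must be >= 0")
        if self.fp_per_megapixel < 0:
            raise ConfigError("fp_per_megapixel must be >= 0")

    @classmethod
    def perfect(cls, **overrides) -> "SimConfig":
        """Noise-free limit: every object found exactly, score 1, no FPs."""
        base = dict(p_detect=1.0, center_jitter_sd=0.0, radius_jitter_sd=0.0,
                    fp_per_megapixel=0.0, tp_score_params=None)
        base.update(overrides)
        return cls(**base)


def generate_ground_truth(cfg: SimConfig) -> list[Circle]:
    """Place ``n_gt`` non-overlapping circles fully inside the slide.

    Radii uniform in ``radius_range``; centers uniform with a margin of one
    radius from every edge; minimum pairwise center distance
    ``min_separation`` enforced by rejection sampling (bounded attempts).
    Deterministic at fixed seed.
    """
    rng = np.random.default_rng([int(cfg.seed), 0xC1AC1E])
    placed: list[Circle] = []
    max_attempts = 10_000 + 1_000 * cfg.n_gt
    attempts = 0
    rmin, rmax = cfg.radius_range
    while len(placed) < cfg.n_gt:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {cfg.n_gt} circles with min_separation="
                f"{cfg.min_separation} on a {cfg.width}x{cfg.height} slide; "
                "use fewer or smaller circles")
        attempts += 1
        r = rng.uniform(rmin, rmax)
        if cfg.width - 2 * r <= 0 or cfg.height - 2 * r <= 0:
            continue
        cx = rng.uniform(r, cfg.width - r)
        cy = rng.uniform(r, cfg.height - r)
        if all((cx - p.cx) ** 2 + (cy - p.cy) ** 2 >= cfg.min_separation ** 2
               for p in placed):
            placed.append(Circle(cx=cx, cy=cy, r=r))
    return placed


def _model_rng(cfg: SimConfig, model_index: int, seed: int | None) -> np.random.Generator:
    base = cfg.seed if seed is None else seed
    return np.random.default_rng([int(base), 1 + int(model_index)])


def simulate_detector(gt: Sequence[Circle], cfg: SimConfig, model_index: int,
                      seed: int | None = None) -> list[Circle]:
    """One noisy detector's output over the slide, in the global frame.

    Each ground-truth circle is found with probability ``p_detect``; found
    copies get isotropic Gaussian center jitter, multiplicative radius
    jitter and a Beta-distributed confidence.  False positives are added as
    a Poisson count proportional to slide area, with random geometry and
    their own confidence distribution; its default decreasing density with a
    heavy upper tail models the occasional high-confidence hard negative,
    so confidence ranking alone cannot separate false from true detections.
    """
    rng = _model_rng(cfg, model_index, seed)
    model_id = f"model_{model_index + 1}"
    out: list[Circle] = []
    rmin, rmax = cfg.radius_range

    for g in gt:
        if rng.random() >= cfg.p_detect:
            continue
        cx = g.cx + rng.normal(0.0, cfg.center_jitter_sd) if cfg.center_jitter_sd else g.cx
        cy = g.cy + rng.normal(0.0, cfg.center_jitter_sd) if cfg.center_jitter_sd else g.cy
        factor = 1.0 + (rng.normal(0.0, cfg.radius_jitter_sd) if cfg.radius_jitter_sd else 0.0)
        r = max(g.r * factor, 1e-3)
        cx = float(np.clip(cx, 0.0, cfg.width))
        cy = float(np.clip(cy, 0.0, cfg.height))
        if cfg.tp_score_params is None:
            score = 1.0
        else:
            score = float(rng.beta(*cfg.tp_score_params))
        out.append(Circle(cx=cx, cy=cy, r=r, score=score, model_id=model_id))

    mp = cfg.width * cfg.height / 1e6
    n_fp = int(rng.poisson(cfg.fp_per_megapixel * mp)) if cfg.fp_per_megapixel else 0
    for _ in range(n_fp):
        r = rng.uniform(rmin, rmax)
        cx = rng.uniform(r, max(cfg.width - r, r))
        cy = rng.uniform(r, max(cfg.height - r, r))
        score = float(rng.beta(*cfg.fp_score_params))
        out.append(Circle(cx=float(cx), cy=float(cy), r=float(r),
                          score=score, model_id=model_id))
    return out


@dataclass(frozen=True)
class Benchmark:
    """One simulated slide plus the full ensemble's detections."""

    ground_truth: tuple[Circle, ...]
    per_model: Mapping[str, tuple[Circle, ...]]
    manifest: dict

    @property
    def model_ids(self) -> list[str]:
        return list(self.per_model)


def make_ensemble_benchmark(cfg: SimConfig | None = None) -> Benchmark:
    """Bundle one ground-truth set with ``n_models`` detector outputs.

    The manifest records every parameter and the seed, so a bundle is
    reproducible byte-for-byte.
    """
    cfg = cfg or SimConfig()
    gt = generate_ground_truth(cfg)
    per_model = {f"model_{i + 1}": tuple(simulate_detector(gt, cfg, i))
                 for i in range(cfg.n_models)}
    manifest = {"config": asdict(cfg), "n_gt": len(gt),
                "detections_per_model": {m: len(v) for m, v in per_model.items()}}
    return Benchmark(ground_truth=tuple(gt), per_model=per_model, manifest=manifest)


class PrecomputedDetector:
    """Serve slide-global detections as a per-patch detector.

    Given a patch window, returns (patch-local copies of) every detection
    whose center falls inside the window — mimicking a patch-based detector
    applied to a slide whose objects are known.  Objects in overlap regions
    are returned by every covering patch, producing exactly the duplicates
    cross-patch NMS must collapse.
    """

    def __init__(self, model_id: str, detections: Sequence[Circle]):
        self.model_id = model_id
        self._dets = [c if c.model_id else
                      Circle(c.cx, c.cy, c.r, score=c.score, model_id=model_id,
                             category=c.category)
                      for c in detections]

    def __call__(self, patch: PatchSpec) -> list[Circle]:
        out = []
        for c in self._dets:
            if (patch.x0 <= c.cx < patch.x0 + patch.size
                    and patch.y0 <= c.cy < patch.y0 + patch.size):
                out.append(c.translated(-patch.x0, -patch.y0))
        return out


def write_bundle(bench: Benchmark, out_dir: str | Path) -> None:
    """Write a bundle to disk: GT CSV, per-model detection CSVs, YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slide = str(bench.manifest.get("slide", "sim_slide"))
    write_detections_csv(
        frame_from_circles((slide, c) for c in bench.ground_truth),
        out / "ground_truth.csv")
    for model_id, dets in bench.per_model.items():
        write_detections_csv(
            frame_from_circles((slide, c) for c in dets),
            out / f"detections_{model_id}.csv")
    (out / "manifest.yaml").write_text(yaml.safe_dump(bench.manifest, sort_keys=True))


def read_bundle(bundle_dir: str | Path) -> Benchmark:
    """Read a bundle written by :func:`write_bundle`."""
    d = Path(bundle_dir)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    gt = tuple(c for _, c in circles_from_frame(
        read_detections_csv(d / "ground_truth.csv")))
    per_model = {}
    for f in sorted(d.glob("detections_model_*.csv")):
        model_id = f.stem.removeprefix("detections_")
        per_model[model_id] = tuple(c for _, c in
                                    circles_from_frame(read_detections_csv(f)))
    return Benchmark(ground_truth=gt, per_model=per_model, manifest=manifest)
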