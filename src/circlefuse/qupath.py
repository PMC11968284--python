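"""Interchange with the QuPath annotation ecosystem.

Fused circles are exported as an RFC 7946 GeoJSON FeatureCollection in the
dialect QuPath imports: each circle becomes a Polygon approximating the
circle as a regular 64-gon (closed, counterclockwise ring of pixel [x, y]
pairs) with an ``objectType: "annotation"`` property and a classification
block named ``fused_k`` — k being the number of distinct models that
supported the detection — coloured so reviewers can spot low-consensus
circles at a glance.  The exact circle parameters (cx, cy, r, score,
model_count) are duplicated as plain properties so a write/read round trip
is lossless; a reader encountering an externally edited, polygon-only
feature falls back to a least-squares circle fit.

Plain CSV detection tables (header ``slide,model_id,cx,cy,r,score``) are the
second interchange surface, used for precomputed detections and benchmark
bundles.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .fusion import FusedCircle
from .geometry import Circle

__all__ = [
    "Palette", "write_geojson", "read_geojson",
    "write_detections_csv", "read_detections_csv",
    "circles_from_frame", "frame_from_circles",
    "write_fused_csv", "read_fused_csv",
]

logger = logging.getLogger(__name__)

N_VERTICES = 64

CSV_COLUMNS = ["slide", "model_id", "cx", "cy", "r", "score"]
FUSED_COLUMNS = ["slide", "cx", "cy", "r", "score", "model_count"]

# Maximally distinct defaults for consensus counts 1..5; count 1 (single
# model, most suspect) is red, full consensus is green.
_DEFAULT_COLORS: dict[int, tuple[int, int, int]] = {
    1: (230, 25, 75),
    2: (245, 130, 48),
    3: (255, 225, 25),
    4: (66, 103, 245),
    5: (60, 180, 75),
}
_FALLBACK_COLOR = (128, 128, 128)


@dataclass(frozen=True)
class Palette:
    """model_count → display colour (RGB triple); distinct counts get distinct colours."""

    colors: Mapping[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_COLORS))

    def color_for(self, model_count: int) -> tuple[int, int, int]:
        return tuple(self.colors.get(model_count, _FALLBACK_COLOR))


def _ring(cx: float, cy: float, r: float, n: int = N_VERTICES) -> list[list[float]]:
    """Closed counterclockwise 64-gon ring (positive shoelace area)."""
    pts = []
    for k in range(n):
        theta = 2.0 * math.pi * k / n
        pts.append([cx + r * math.cos(theta), cy + r * math.sin(theta)])
    pts.append(list(pts[0]))
    return pts


def write_geojson(fused: Sequence[FusedCircle], path: str | Path,
                  palette: Palette | None = None) -> None:
    """Write fused circles (slide-global frame) as a QuPath-dialect FeatureCollection."""
    palette = palette or Palette()
    features = []
    for f in fused:
        color = palette.color_for(f.model_count)
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [_ring(f.cx, f.cy, f.r)],
            },
            "properties": {
                "objectType": "annotation",
                "classification": {
                    "name": f"fused_{f.model_count}",
                    "color": list(color),
                },
                "cx": f.cx,
                "cy": f.cy,
                "r": f.r,
                "score": f.fused_score,
                "model_count": f.model_count,
            },
        })
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=1))


def fit_circle(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (Kåsa) circle fit to a point ring.

    Solves the linear system for cx, cy and r from x² + y² = 2·cx·x +
    2·cy·y + (r² − cx² − cy²); exact for points on a true circle and robust
    for regular polygons approximating one.
    """
    A = np.column_stack([2.0 * xs, 2.0 * ys, np.ones_like(xs)])
    b = xs * xs + ys * ys
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx * cx + cy * cy, 0.0))
    return float(cx), float(cy), float(r)


_COUNT_RE = re.compile(r"^fused_(\d+)$")


def read_geojson(path: str | Path) -> list[FusedCircle]:
    """Read a FeatureCollection back into fused circles.

    Prefers the exact cx/cy/r properties the writer emits; falls back to a
    least-squares circle fit on the polygon ring for externally edited
    features.  Malformed features are skipped with a warning and counted.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise SchemaError("expected a GeoJSON FeatureCollection")
    out: list[FusedCircle] = []
    n_skipped = 0
    for i, feat in enumerate(doc.get("features", [])):
        try:
            props = feat.get("properties") or {}
            if all(k in props for k in ("cx", "cy", "r")):
                cx, cy, r = float(props["cx"]), float(props["cy"]), float(props["r"])
            else:
                ring = feat["geometry"]["coordinates"][0]
                pts = np.asarray(ring[:-1], dtype=float)
                cx, cy, r = fit_circle(pts[:, 0], pts[:, 1])
            score = props.get("score")
            score = float(score) if score is not None else None
            count = props.get("model_count")
            if count is None:
                name = (props.get("classification") or {}).get("name", "")
                m = _COUNT_RE.match(name)
                count = int(m.group(1)) if m else 1
            circle = Circle(cx=cx, cy=cy, r=r, score=score)
            out.append(FusedCircle(circle=circle,
                                   fused_score=score if score is not None else 0.0,
                                   members=(), model_count=int(count)))
        except Exception as exc:
            n_skipped += 1
            logger.warning("skipping malformed feature %d: %s", i, exc)
    if n_skipped:
        logger.warning("read_geojson skipped %d malformed feature(s)", n_skipped)
    return out


# ---------------------------------------------------------------------------
# CSV detection tables


def frame_from_circles(records: Iterable[tuple[str, Circle]]) -> pd.DataFrame:
    """Tabulate (slide, circle) records with the canonical column order."""
    rows = [{"slide": slide, "model_id": c.model_id, "cx": c.cx, "cy": c.cy,
             "r": c.r, "score": c.score} for slide, c in records]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def circles_from_frame(df: pd.DataFrame) -> list[tuple[str, Circle]]:
    """Inverse of :func:`frame_from_circles`."""
    out = []
    for row in df.itertuples(index=False):
        score = None if pd.isna(row.score) else float(row.score)
        model_id = None if pd.isna(row.model_id) else str(row.model_id)
        out.append((str(row.slide),
                    Circle(cx=float(row.cx), cy=float(row.cy), r=float(row.r),
                           score=score, model_id=model_id)))
    return out


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def write_detections_csv(records: Iterable[tuple[str, Circle]] | pd.DataFrame,
                         path: str | Path) -> None:
    """Write a detection table; floats serialised with 6 decimals."""
    df = records if isinstance(records, pd.DataFrame) else frame_from_circles(records)
    _check_columns(df, CSV_COLUMNS, path)
    df.to_csv(path, index=False, float_format="%.6f")


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    """Read a detection table, validating the schema."""
    df = pd.read_csv(path)
    _check_columns(df, CSV_COLUMNS, path)
    return df


def write_fused_csv(fused: Sequence[FusedCircle], path: str | Path,
                    slide: str = "slide") -> None:
    rows = [{"slide": slide, "cx": f.cx, "cy": f.cy, "r": f.r,
             "score": f.fused_score, "model_count": f.model_count}
            for f in fused]
    pd.DataFrame(rows, columns=FUSED_COLUMNS).to_csv(path, index=False,
                                                     float_format="%.6f")


def read_fused_csv(path: str | Path) -> list[tuple[str, FusedCircle]]:
    df = pd.read_csv(path)
    _check_columns(df, FUSED_COLUMNS, path)
    out = []
    for row in df.itertuples(index=False):
        circle = Circle(cx=float(row.cx), cy=float(row.cy), r=float(row.r),
                        score=float(row.score))
        out.append((str(row.slide),
                    FusedCircle(circle=circle, fused_score=float(row.score),
                                members=(), model_count=int(row.model_count))))
    return out
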