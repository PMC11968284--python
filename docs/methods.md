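# Methods

## Problem setting

Glomeruli in histology sections are near-circular, so a detector that
predicts circles (center, radius, confidence) is a natural fit and makes
the representation rotation-consistent. A whole-slide image is far too
large for a single forward pass, so detection is patch-based; and single
models trained on one data subset are noisy, so an ensemble of models with
varied training data is fused into one consensus result. `circlefuse`
implements that post-processing chain — tiling, coordinate transforms,
deduplication, ensemble fusion, scoring, and interchange — as a library
plus CLI, with detectors abstracted behind a per-patch callable so the
chain runs identically on real model outputs (via CSV) or on synthetic
detectors.

## Geometry

Circle IoU is computed analytically. With center distance d and radii
r_a ≤ r_b: IoU = 0 when d ≥ r_a + r_b; the area ratio r_a²/r_b² when
d ≤ r_b − r_a (containment); otherwise the circular-lens intersection

    I = r_a² acos((d² + r_a² − r_b²) / 2dr_a)
      + r_b² acos((d² + r_b² − r_a²) / 2dr_b)
      − ½ √((−d+r_a+r_b)(d+r_a−r_b)(d−r_a+r_b)(d+r_a+r_b))

over the union A_a + A_b − I. Numerical guards: acos arguments are clamped
to [−1, 1] and the Heron-style product to ≥ 0, so tangency and containment
boundaries never produce NaNs; identical circles return exactly 1.0; and
operands are put in a canonical order before evaluation so
iou(a, b) == iou(b, a) holds exactly, not just to rounding.

## Suppression

Hard NMS is greedy by descending confidence: a detection is removed iff its
IoU with an already-kept detection exceeds the threshold (default 0.5).
Soft-NMS decays competitors' scores by exp(−IoU²/σ) (Gaussian variant,
σ = 0.5) and drops scores below a floor (0.001). Ties in confidence are
broken lexicographically by (cx, cy, r), which makes both procedures
invariant to input permutation. Soft-NMS exists here as a comparison
baseline; the pipeline itself uses hard NMS, whose job is collapsing the
near-identical duplicates produced when overlapping patches each detect
the same object.

## Weighted circle fusion

All models' (already deduplicated) detections are pooled and processed in
descending score order. Each detection joins the first existing cluster
whose *current fused circle* overlaps it with IoU > `t_iou` (default 0.5),
else it opens a cluster. A cluster's fused geometry is the score-weighted
mean of member (cx, cy, r), recomputed as members join; its fused score is
the arithmetic mean of member scores. Two filters follow: clusters
supported by fewer than `t_count = 2` distinct models are dropped
(consensus), then clusters with fused score < `t_score = 0.9` are dropped
(confidence). Both defaults are the method's standard operating point.

Design choices that were genuinely open, and how they were resolved:

- *Cluster matching target*: against the running fused circle rather than
  the first member, following the weighted-boxes-fusion convention adapted
  to circles; the alternative is one flag away in the code's structure but
  not exposed, as the two differ only in pathological geometries.
- *Fused confidence*: arithmetic mean by default (`score_mode="mean"`),
  with the score-weighted mean available, since either reading is
  defensible; the confidence filter applies to the averaged value.
- *Sub-consensus clusters*: dropped by default but retrievable
  (`drop_below_count=False`), because the review workflow colour-codes
  detections by supporting-model count 1..n rather than deleting them.
- *Geometry weighting*: confidence weights by default; `"uniform"` is
  provided for sensitivity checks.

## Slide pipeline

Tiling uses 512-px patches with 256-px stride (half overlap) by default;
per axis, origins step by the stride while a full patch fits, and a final
patch is anchored flush with the slide edge when the grid stops short.
Consequences used by the tests: the union of patches covers the slide,
interior pixels are covered exactly four times at half overlap, and any
object with diameter < patch/2 lying inside the slide fits wholly in at
least one patch — the reason boundary objects are not missed. Patch
windows are half-open with integer origins; detections are continuous.
Per-model cross-patch deduplication runs once on each model's pooled
global detections (not per patch), since duplicates arise precisely across
patch overlaps; fusion then counts distinct models, never duplicate
patches. A detector that raises on a patch loses that patch only; the run
completes with partial results and a report of skips.

## Evaluation

Matching follows the COCO convention with circle IoU: detections in
descending score order each claim the highest-IoU unmatched ground truth
at or above the threshold; each ground truth is claimed once. AP uses
101-point interpolation by default (the all-point exact area is available
and used for hand-checkable cases); mAP@[.5:.95] is the mean of the ten
per-threshold APs; average recall is the mean over the grid of the
recalled ground-truth fraction, capped at `max_dets = 500` detections per
slide (well above the ~137 objects a slide carries in this setting).
Degenerate cases are explicit: no ground truth and no detections is an
*undefined* result (None-valued, flagged), not a perfect one; detections
with no ground truth score 0. Multi-slide aggregation averages per-slide
metrics over slides with at least one ground-truth object; a pooled mode
(one joint PR curve over offset-separated slides) is available behind a
flag.

## Synthetic benchmark

The generator emulates the deployment conditions: a 4096×4096-px virtual
slide with 130 non-overlapping ground-truth circles (radii 40–120 px,
min center separation 260 px — circles fit comfortably inside 512-px
patches and do not overlap, mirroring glomerular anatomy; ~130 objects
matches the order of magnitude of glomeruli per slide in typical
evaluation sets), scanned by five detectors with:

- detection probability 0.9 per object,
- isotropic center jitter sd 3 px, multiplicative radius jitter sd 5 %,
- 2 false positives per megapixel (Poisson),
- true-positive confidences Beta(40, 2) (mean ≈ 0.95, so the 0.9 fused-
  confidence threshold is a live constraint: a slide typically loses about
  one true object to it),
- false-positive confidences Beta(0.5, 1.0) — a decreasing density with
  mean 1/3 whose upper tail (≈5 % above 0.9) models high-confidence hard
  negatives. This tail is the crux of the benchmark: with it, confidence
  ranking alone cannot separate false from true detections, so pooled
  NMS/Soft-NMS baselines pay a precision cost that model-consensus
  filtering does not, which is exactly the regime the fusion method is
  designed for.

Per-model randomness comes from independent seed streams derived from
(seed, model index), so adding a model never changes the others' outputs.
What the generator does *not* emulate: pixel appearance, stain variation,
correlated errors between models (models sharing training data miss the
same hard objects), spatially clustered false positives, and non-circular
or overlapping objects. Passing the synthetic benchmark therefore
demonstrates the correctness and the qualitative behaviour of the
post-processing chain, not the accuracy of any real detector ensemble.

## Problem sizes and numerics

The test suite and the acceptance study run the benchmark at its default
size (130 objects, five models, ~160 detections per model) over 100
simulated slides — large enough for stable means, small enough for a
laptop CPU. The analytic IoU is validated against a Monte-Carlo
hit-counting oracle (10⁷ samples per pair, ratio estimator over the union
bounding box, agreement within 1e-3). Suppression, fusion, and evaluation
are validated against literal brute-force reference implementations.
Floating-point policy: deterministic tie-breaks everywhere (score, then
cx, cy, r), exact symmetry of IoU by canonical operand ordering, and exact
global→local→global coordinate round trips (pure translation by integer
patch origins).

## Interchange

GeoJSON output approximates each circle as a regular 64-gon (closed,
counterclockwise ring) because the annotation dialect has no native circle
geometry; the exact cx/cy/r/score/model_count are duplicated as feature
properties so round trips are lossless, and a reader encountering
polygon-only features (externally edited) falls back to a least-squares
(Kåsa) circle fit, which is within 0.2 % of the true radius for a regular
64-gon. Coordinates are pixels, never microns; a resolution scale factor
is metadata only. CSV tables are the second surface
(`slide,model_id,cx,cy,r,score`, six-decimal floats).

## Known limitations

- No real-WSI pixel adapter is bundled; real detections enter via CSV.
- Fusion is single-class; cross-class ensembles are out of scope.
- The consensus filter assumes model errors are independent; correlated
  ensembles (shared backbones or data) weaken its false-positive removal,
  and the benchmark does not model that correlation.
- Per-slide AP averaging is the default; pooled-dataset AP can differ and
  is available explicitly.
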