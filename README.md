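# circlefuse

Post-processing toolkit for circle-based object detection on whole-slide
images (WSIs), built around the detection workflow used for glomeruli in
renal pathology. Detectors in this setting predict **circles** — a center
(cx, cy) and radius r with a confidence score — rather than bounding boxes,
because glomeruli are near-circular and a circle is rotation-consistent.
`circlefuse` implements everything that happens *after* (or instead of) the
CNN forward pass:

- **Tiling** a gigapixel slide into square patches overlapping by half
  their area, so objects on patch borders are always fully contained in a
  neighbouring patch, and mapping patch-local detections back to the slide
  frame.
- **Circle IoU**: exact intersection-over-union of two discs (lens
  formula), the overlap metric used throughout.
- **NMS and Soft-NMS** on circles, both for collapsing duplicate detections
  from overlapping patches and as baseline ensemble methods.
- **Weighted circle fusion (WCF)**: the ensemble step. Detections from
  several independently trained models are clustered by circle IoU; each
  cluster is merged into one circle whose geometry is the confidence-
  weighted mean of its members, with the arithmetic-mean confidence.
  A fused detection is kept only if it is supported by at least
  `t_count = 2` distinct models and its fused confidence reaches
  `t_score = 0.9`. Because false positives are largely model-independent
  while real objects are found by most models, the consensus filter
  removes false positives that confidence thresholds alone cannot.
- **Evaluation**: COCO-style greedy matching under circle IoU, average
  precision per threshold, mAP over IoU 0.50–0.95 (step 0.05), and average
  recall.
- **QuPath interchange**: fused circles exported as GeoJSON
  FeatureCollections (64-gon polygons, classification `fused_k` coloured
  by supporting-model count so low-consensus detections are easy to
  review), plus plain CSV detection tables.
- **Synthetic benchmark**: a generator for virtual slides with
  non-overlapping ground-truth circles and a parameterised ensemble of
  noisy detectors (miss rate, localisation jitter, false-positive rate,
  Beta-distributed confidences), so the whole pipeline is testable with no
  slides, weights, or downloads.

Intended users: computational-pathology researchers and tool builders who
have per-patch or per-slide circle detections (from any detector) and need
robust fusion, scoring, and QuPath-ready output.

## Worked example

Three models looked at the same slide region; two regions have multi-model
support, a third was seen by a single model only:

```python
from circlefuse import Circle, FusionConfig, wcf, categorize_by_count

dets = {
    "model_1": [Circle(1012.0, 640.0, 58.0, score=0.97),
                Circle(2203.0, 1110.0, 75.0, score=0.95)],
    "model_2": [Circle(1016.0, 643.0, 60.0, score=0.93),
                Circle(2200.0, 1114.0, 73.0, score=0.96)],
    "model_3": [Circle(1014.0, 641.0, 59.0, score=0.99),
                Circle(3050.0, 410.0, 44.0, score=0.88)],
}
fused = wcf(dets, FusionConfig(t_count=2, t_score=0.9))
for f in fused:
    print(f"center=({f.cx:.1f}, {f.cy:.1f})  r={f.r:.1f}  "
          f"score={f.fused_score:.3f}  models={f.model_count}")
print({k: len(v) for k, v in categorize_by_count(fused).items()})
```

prints

```
center=(1014.0, 641.3)  r=59.0  score=0.963  models=3
center=(2201.5, 1112.0)  r=74.0  score=0.955  models=2
{'fused_3': 1, 'fused_2': 1}
```

The two circles seen by multiple models were merged into confidence-
weighted consensus circles; the detection at (3050, 410) appeared in only
one model's output, fails the two-model consensus requirement, and is
dropped. `categorize_by_count` gives the grouping QuPath displays with one
colour per supporting-model count.

## Command line

```bash
circlefuse simulate --seed 7 --out-dir bundle        # synthetic benchmark bundle
circlefuse fuse bundle/detections_model_*.csv --out-dir fused
circlefuse eval fused/fused.csv bundle/ground_truth.csv --out report.csv
circlefuse run bundle --out-dir out                  # tile→detect→NMS→WCF→eval
```

Detection CSVs use the header `slide,model_id,cx,cy,r,score` in slide-global
pixel coordinates, so precomputed detections from any real detector can be
fused and scored the same way.

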