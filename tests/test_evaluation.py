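"""Greedy matching, AP interpolation, and aggregate metrics vs references."""

import math

import numpy as np
import pytest

from circlefuse.evaluation import (EvalConfig, average_precision, evaluate,
                                   evaluate_dataset, match_detections)
from circlefuse.geometry import Circle

from oracles import ap_101, brute_match, random_circles


def test_coincident_detection_is_tp():
    g = Circle(50, 50, 20)
    d = Circle(50, 50, 20, score=0.9)
    m = match_detections([d], [g], 0.5)
    assert m.tp == (True,) and m.gt_matched == (True,)


def test_second_coincident_detection_is_fp():
    g = Circle(50, 50, 20)
    d1 = Circle(50, 50, 20, score=0.9)
    d2 = Circle(50, 50, 20, score=0.8)
    m = match_detections([d1, d2], [g], 0.5)
    assert m.tp == (True, False)


def test_matching_agrees_with_brute_force(rng):
    for _ in range(40):
        n_det = int(rng.integers(0, 31))
        n_gt = int(rng.integers(0, 21))
        dets = random_circles(rng, n_det, extent=400.0, r_lo=10, r_hi=50)
        gts = random_circles(rng, n_gt, extent=400.0, r_lo=10, r_hi=50,
                             scored=False)
        for thr in (0.3, 0.5, 0.75):
            m = match_detections(dets, gts, thr)
            order, tp, taken = brute_match(dets, gts, thr)
            assert m.order == tuple(order)
            assert m.tp == tuple(tp)
            assert m.gt_matched == tuple(taken)


def test_ap_perfect_detector_is_one():
    assert average_precision([True] * 7, 7, "all-point") == pytest.approx(1.0)
    assert average_precision([True] * 7, 7, "101-point") == pytest.approx(1.0)


def test_ap_tp_fp_half():
    assert average_precision([True, False], 2, "all-point") == pytest.approx(0.5)
    got = average_precision([True, False], 2, "101-point")
    assert got == pytest.approx(51 / 101)


def test_ap_101_matches_direct_summation(rng):
    for _ in range(30):
        n = int(rng.integers(1, 40))
        flags = list(rng.random(n) < 0.6)
        n_gt = max(int(sum(flags)), int(rng.integers(1, 30)))
        got = average_precision(flags, n_gt, "101-point")
        assert got == pytest.approx(ap_101(flags, n_gt), abs=1e-12)


def test_ap_degenerate_ground_truth():
    assert average_precision([], 0) is None
    assert average_precision([False, False], 0) == 0.0
    assert average_precision([], 5) == 0.0


def test_evaluate_perfect_and_disjoint():
    gts = [Circle(100, 100, 30), Circle(300, 300, 40)]
    perfect = [g.with_score(0.9) for g in gts]
    res = evaluate(perfect, gts)
    assert res.map_50 == res.map_75 == res.map_50_95 == 1.0
    assert res.average_recall == 1.0

    far = [Circle(700, 700, 10, score=0.8)]
    res = evaluate(far, gts)
    assert res.map_50_95 == 0.0 and res.average_recall == 0.0


def test_evaluate_empty_both_is_undefined():
    res = evaluate([], [])
    assert not res.defined
    assert res.map_50 is None and res.average_recall is None


def test_map_50_95_is_mean_of_thresholds(rng):
    dets = random_circles(rng, 40, extent=500.0, r_lo=10, r_hi=60)
    gts = random_circles(rng, 25, extent=500.0, r_lo=10, r_hi=60, scored=False)
    res = evaluate(dets, gts)
    vals = [v for v in res.ap_by_threshold.values() if v is not None]
    assert res.map_50_95 == pytest.approx(float(np.mean(vals)), abs=1e-12)
    assert res.ap_by_threshold[0.5] == res.map_50
    assert res.ap_by_threshold[0.75] == res.map_75


def test_ap_non_increasing_in_threshold(rng):
    # Tighter IoU thresholds can only lose matches.
    dets = [g.translated(rng.normal(0, 5), rng.normal(0, 5)).with_score(
        float(rng.uniform(0.2, 1)))
        for g in random_circles(rng, 30, extent=800.0, r_lo=20, r_hi=60,
                                scored=False)]
    gts = random_circles(rng, 30, extent=800.0, r_lo=20, r_hi=60, scored=False)
    res = evaluate(dets, gts)
    aps = [res.ap_by_threshold[t] for t in sorted(res.ap_by_threshold)]
    assert all(b <= a + 1e-12 for a, b in zip(aps, aps[1:]))


def test_score_scale_invariance(rng):
    dets = random_circles(rng, 30, extent=400.0)
    gts = random_circles(rng, 20, extent=400.0, scored=False)
    base = evaluate(dets, gts)
    scaled = evaluate([c.with_score(c.score * 0.37) for c in dets], gts)
    assert scaled.ap_by_threshold == base.ap_by_threshold
    assert scaled.average_recall == base.average_recall


def test_rotation_consistency(rng):
    cx0 = cy0 = 500.0

    def rot90(c: Circle) -> Circle:
        dx, dy = c.cx - cx0, c.cy - cy0
        return Circle(cx0 - dy, cy0 + dx, c.r, score=c.score)

    dets = random_circles(rng, 40, extent=1000.0)
    gts = random_circles(rng, 30, extent=1000.0, scored=False)
    base = evaluate(dets, gts)
    rot = evaluate([rot90(c) for c in dets], [rot90(c) for c in gts])
    for t, v in base.ap_by_threshold.items():
        assert rot.ap_by_threshold[t] == pytest.approx(v, abs=1e-12)
    assert rot.average_recall == pytest.approx(base.average_recall, abs=1e-12)


def test_max_dets_caps_scored_detections():
    gts = [Circle(100 * (i + 1), 100, 20) for i in range(4)]
    dets = [g.with_score(0.9 - 0.1 * i) for i, g in enumerate(gts)]
    res = evaluate(dets, gts, EvalConfig(max_dets=2))
    assert res.average_recall == pytest.approx(0.5)


def test_dataset_per_slide_average_and_pooled(rng):
    gts = {"s1": random_circles(rng, 10, extent=300.0, scored=False),
           "s2": random_circles(rng, 8, extent=300.0, scored=False),
           "empty": []}
    dets = {"s1": [g.with_score(0.9) for g in gts["s1"]],
            "s2": [],
            "empty": []}
    per_slide, agg = evaluate_dataset(dets, gts)
    assert per_slide["s1"].map_50 == 1.0
    assert per_slide["s2"].map_50 == 0.0
    # Slides without ground truth are excluded from the aggregate.
    assert agg.map_50 == pytest.approx(0.5)
    _, pooled = evaluate_dataset(dets, gts, pooled=True)
    # Pooled: 10 of 18 ground truths recalled at precision 1.
    assert pooled.ap_by_threshold[0.5] == pytest.approx(
        average_precision([True] * 10, 18, "101-point"))
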