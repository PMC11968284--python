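"""The synthetic benchmark generator: determinism, constraints, noise model."""

import numpy as np
import pytest

from circlefuse.errors import ConfigError, PackingError
from circlefuse.evaluation import evaluate
from circlefuse.fusion import FusionConfig, wcf
from circlefuse.pipeline import SlideMeta, run_pipeline
from circlefuse.simulate import (Benchmark, PrecomputedDetector, SimConfig,
                                 generate_ground_truth, make_ensemble_benchmark,
                                 read_bundle, simulate_detector, write_bundle)
from circlefuse.suppression import SuppressionConfig, nms


def test_ground_truth_constraints():
    cfg = SimConfig(n_gt=100, seed=5)
    gt = generate_ground_truth(cfg)
    assert len(gt) == 100
    for c in gt:
        assert cfg.radius_range[0] <= c.r <= cfg.radius_range[1]
        assert c.r <= c.cx <= cfg.width - c.r
        assert c.r <= c.cy <= cfg.height - c.r
        assert c.score is None
    for i, a in enumerate(gt):
        for b in gt[i + 1:]:
            d = np.hypot(a.cx - b.cx, a.cy - b.cy)
            assert d >= cfg.min_separation


def test_ground_truth_empty_and_deterministic():
    assert generate_ground_truth(SimConfig(n_gt=0)) == []
    a = generate_ground_truth(SimConfig(seed=42))
    b = generate_ground_truth(SimConfig(seed=42))
    assert a == b
    c = generate_ground_truth(SimConfig(seed=43))
    assert a != c


def test_infeasible_packing_raises():
    with pytest.raises(PackingError):
        generate_ground_truth(SimConfig(width=600, height=600, n_gt=50,
                                        radius_range=(100, 120),
                                        min_separation=400.0))


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        SimConfig(p_detect=1.5)
    with pytest.raises(ConfigError):
        SimConfig(radius_range=(0.0, 10.0))
    with pytest.raises(ConfigError):
        SimConfig(fp_per_megapixel=-1.0)


def test_noise_free_detector_reproduces_truth():
    cfg = SimConfig.perfect(seed=1)
    gt = generate_ground_truth(cfg)
    dets = simulate_detector(gt, cfg, model_index=0)
    assert len(dets) == len(gt)
    for g, d in zip(gt, dets):
        assert (d.cx, d.cy, d.r) == (g.cx, g.cy, g.r)
        assert d.score == 1.0
        assert d.model_id == "model_1"


def test_p_detect_zero_no_fp_is_empty():
    cfg = SimConfig(p_detect=0.0, fp_per_megapixel=0.0, seed=1)
    gt = generate_ground_truth(cfg)
    assert simulate_detector(gt, cfg, model_index=0) == []


def test_detection_count_matches_binomial_expectation():
    # n_gt=200, p_detect=0.9 over many independent seeds: the mean count
    # must sit within 3 standard errors of 180.
    cfg = SimConfig(width=8192, height=8192, n_gt=200, min_separation=250.0,
                    p_detect=0.9, fp_per_megapixel=0.0, seed=2)
    gt = generate_ground_truth(cfg)
    n_rep = 1000
    counts = [len(simulate_detector(gt, cfg, model_index=0, seed=s))
              for s in range(n_rep)]
    se = np.sqrt(200 * 0.9 * 0.1 / n_rep)
    assert abs(np.mean(counts) - 180.0) <= 3 * se


def test_per_model_streams_independent():
    cfg = SimConfig(seed=9)
    gt = generate_ground_truth(cfg)
    m0_before = simulate_detector(gt, cfg, model_index=0)
    m1 = simulate_detector(gt, cfg, model_index=1)
    m0_after = simulate_detector(gt, cfg, model_index=0)
    assert m0_before == m0_after
    assert m0_before != m1


def test_benchmark_reproducible_and_within_bounds(tmp_path):
    cfg = SimConfig(width=2048, height=2048, n_gt=40, min_separation=220.0,
                    seed=17)
    b1 = make_ensemble_benchmark(cfg)
    b2 = make_ensemble_benchmark(cfg)
    assert b1.ground_truth == b2.ground_truth
    assert dict(b1.per_model) == dict(b2.per_model)
    for dets in b1.per_model.values():
        for c in dets:
            assert 0 <= c.cx <= cfg.width and 0 <= c.cy <= cfg.height
            assert 0.0 <= c.score <= 1.0

    write_bundle(b1, tmp_path / "bundle")
    back = read_bundle(tmp_path / "bundle")
    assert len(back.ground_truth) == len(b1.ground_truth)
    assert set(back.per_model) == set(b1.per_model)
    for mid in b1.per_model:
        for c0, c1 in zip(b1.per_model[mid], back.per_model[mid]):
            assert (c1.cx, c1.cy, c1.r) == pytest.approx(
                (c0.cx, c0.cy, c0.r), abs=1e-6)


def test_single_model_bundle_evaluates():
    cfg = SimConfig(width=2048, height=2048, n_gt=30, min_separation=220.0,
                    n_models=1, seed=4)
    bench = make_ensemble_benchmark(cfg)
    assert bench.model_ids == ["model_1"]
    res = evaluate(list(bench.per_model["model_1"]), list(bench.ground_truth))
    assert res.defined and 0.0 <= res.map_50 <= 1.0


def test_noise_free_pipeline_identity():
    # With noise off, tile -> detect -> NMS -> WCF (t_score 0) returns the
    # ground truth exactly, every circle at full consensus.
    cfg = SimConfig.perfect(width=1536, height=1536, n_gt=20,
                            min_separation=200.0, seed=8)
    gt = generate_ground_truth(cfg)
    detectors = [PrecomputedDetector(f"model_{i+1}",
                                     simulate_detector(gt, cfg, i))
                 for i in range(cfg.n_models)]
    fused = run_pipeline(SlideMeta(cfg.width, cfg.height), detectors,
                         fusion_cfg=FusionConfig(t_score=0.0))
    assert len(fused) == len(gt)
    assert all(f.model_count == cfg.n_models for f in fused)
    got = sorted((round(f.cx, 9), round(f.cy, 9), round(f.r, 9)) for f in fused)
    want = sorted((round(c.cx, 9), round(c.cy, 9), round(c.r, 9)) for c in gt)
    assert got == want


def test_consensus_removes_independent_false_positives():
    # False positives are model-independent, so raising the consensus
    # threshold from 1 to 2 should remove (essentially) all of them.
    sup = SuppressionConfig()
    rates = {1: [], 2: []}
    for seed in range(5):
        cfg = SimConfig(p_detect=1.0, fp_per_megapixel=4.0, seed=seed)
        bench = make_ensemble_benchmark(cfg)
        gt = list(bench.ground_truth)
        deduped = {m: nms(list(v), sup) for m, v in bench.per_model.items()}
        for t_count in (1, 2):
            fused = wcf(deduped, FusionConfig(t_count=t_count, t_score=0.0))
            dets = [f.circle.with_score(f.fused_score) for f in fused]
            m = evaluate(dets, gt)
            res = sum(1 for f in fused
                      if all(not _near(f, g) for g in gt))
            rates[t_count].append(res)
    assert sum(rates[2]) < 0.05 * max(sum(rates[1]), 1)


def _near(f, g):
    from circlefuse.geometry import circle_iou
    return circle_iou(f.circle, g) >= 0.5
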