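import numpy as np
import pytest

from fishtrack.geometry import centroid, displacement_angle
from fishtrack.movement import Direction, bin_direction
from fishtrack.synthetic import (
    DetectorNoiseConfig,
    SceneConfig,
    gt_frame_boxes,
    render_scene,
    simulate_detections,
    simulate_trajectories,
)


class TestTrajectories:
    def test_constant_velocity_advances_centroids(self):
        cfg = SceneConfig(
            n_targets=1,
            n_frames=20,
            motion_model="constant_velocity",
            velocities=((4.0, 0.0),),
            respawn=False,
            seed=0,
        )
        gt = simulate_trajectories(cfg)
        tid = next(iter(gt))
        frames = sorted(gt[tid])
        cs = [centroid(gt[tid][f]) for f in frames]
        for a, b in zip(cs, cs[1:]):
            assert b.x - a.x == pytest.approx(4.0)
            assert b.y - a.y == pytest.approx(0.0)

    def test_deterministic_given_seed(self):
        cfg = SceneConfig(seed=8, n_frames=15)
        a = simulate_trajectories(cfg)
        b = simulate_trajectories(cfg)
        assert a.keys() == b.keys()
        for tid in a:
            assert {f: x.as_xywh() for f, x in a[tid].items()} == {
                f: x.as_xywh() for f, x in b[tid].items()
            }

    def test_boxes_clipped_to_frame(self):
        cfg = SceneConfig(n_frames=40, seed=2)
        gt = simulate_trajectories(cfg)
        w, h = cfg.frame_size
        for per_frame in gt.values():
            for box in per_frame.values():
                assert box.x >= 0 and box.y >= 0
                assert box.x2 <= w and box.y2 <= h

    def test_tidal_drift_dominance_binned_right(self):
        cfg = SceneConfig(n_frames=500, n_targets=5, drift_dominance=0.9, seed=1)
        gt = simulate_trajectories(cfg)
        n_right = n_total = 0
        for per_frame in gt.values():
            frames = sorted(per_frame)
            for a, b in zip(frames, frames[1:]):
                if b - a != 1:
                    continue
                ang = displacement_angle(centroid(per_frame[a]), centroid(per_frame[b]))
                if ang is None:
                    continue
                n_total += 1
                n_right += bin_direction(ang) == Direction.RIGHT
        assert n_total > 1000
        assert n_right / n_total > 0.8

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(frame_size=(40, 40), target_axes=(30.0, 8.0))


class TestRenderScene:
    def test_bit_identical_for_same_seed(self):
        cfg = SceneConfig(n_frames=4, frame_size=(64, 64), target_axes=(8, 5), seed=6)
        f1, g1 = render_scene(cfg)
        f2, g2 = render_scene(cfg)
        np.testing.assert_array_equal(f1, f2)
        assert g1.keys() == g2.keys()

    def test_gt_matches_trajectory_simulation(self):
        cfg = SceneConfig(n_frames=6, frame_size=(64, 64), target_axes=(8, 5), seed=6)
        _, gt_render = render_scene(cfg)
        gt_sim = simulate_trajectories(cfg)
        assert {t: {f: b.as_xywh() for f, b in v.items()} for t, v in gt_render.items()} == {
            t: {f: b.as_xywh() for f, b in v.items()} for t, v in gt_sim.items()
        }

    def test_targets_brighter_than_background(self):
        cfg = SceneConfig(
            n_targets=1, n_frames=2, frame_size=(96, 96), clutter_rate=0.0, seed=4
        )
        frames, gt = render_scene(cfg)
        tid = next(iter(gt))
        box = gt[tid][0]
        c = centroid(box)
        inside = frames[0][int(c.y), int(c.x)]
        assert inside > cfg.background_level + 50


class TestSimulateDetections:
    def test_noise_free_detections_equal_gt(self):
        cfg = SceneConfig(n_frames=10, n_targets=3, seed=5)
        gt = simulate_trajectories(cfg)
        noise = DetectorNoiseConfig(
            miss_rate=0.0, false_positive_rate=0.0, localization_jitter_sd=0.0
        )
        dets = simulate_detections(gt, noise, cfg.frame_size)
        per_frame = gt_frame_boxes(gt)
        for f, boxes in per_frame.items():
            assert sorted(d.box.as_xywh() for d in dets[f]) == sorted(
                b.as_xywh() for b in boxes
            )
            for d in dets[f]:
                assert 0.0 <= d.confidence <= 1.0

    def test_full_miss_rate_yields_nothing(self):
        cfg = SceneConfig(n_frames=5, seed=5)
        gt = simulate_trajectories(cfg)
        dets = simulate_detections(
            gt,
            DetectorNoiseConfig(miss_rate=1.0, false_positive_rate=0.0),
            cfg.frame_size,
        )
        assert all(len(v) == 0 for v in dets.values())

    def test_miss_rate_binomial_count(self):
        # 10 targets x 100 frames at miss 0.1: expect 900 +/- 3*sqrt(90)
        cfg = SceneConfig(
            n_targets=10,
            n_frames=100,
            frame_size=(600, 400),
            motion_model="constant_velocity",
            velocities=((0.0, 0.0),) * 10,
            respawn=False,
            seed=13,
        )
        gt = simulate_trajectories(cfg)
        assert sum(len(v) for v in gt.values()) == 1000
        noise = DetectorNoiseConfig(miss_rate=0.1, false_positive_rate=0.0, seed=21)
        dets = simulate_detections(gt, noise, cfg.frame_size)
        n = sum(len(v) for v in dets.values())
        assert abs(n - 900) <= 3 * np.sqrt(90)

    def test_determinism(self):
        cfg = SceneConfig(n_frames=8, seed=5)
        gt = simulate_trajectories(cfg)
        noise = DetectorNoiseConfig(seed=3)
        a = simulate_detections(gt, noise, cfg.frame_size)
        b = simulate_detections(gt, noise, cfg.frame_size)
        assert {
            f: [(d.box.as_xywh(), d.confidence) for d in v] for f, v in a.items()
        } == {f: [(d.box.as_xywh(), d.confidence) for d in v] for f, v in b.items()}

    def test_invalid_miss_rate_rejected(self):
        with pytest.raises(ValueError):
            DetectorNoiseConfig(miss_rate=1.5)
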