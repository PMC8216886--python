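import numpy as np
import pytest

from fishtrack.synthetic import SceneConfig, gt_as_detections, render_scene


@pytest.fixture(scope="session")
def single_target_scene():
    """50-frame noise-free-ish scene, one target at constant +3 px/frame."""
    cfg = SceneConfig(
        n_targets=1,
        n_frames=50,
        motion_model="constant_velocity",
        velocities=((3.0, 0.0),),
        clutter_rate=0.0,
        respawn=False,
        seed=3,
    )
    frames, gt = render_scene(cfg)
    return cfg, frames, gt


@pytest.fixture(scope="session")
def five_target_scene():
    """Five never-overlapping targets drifting right, perfect detector."""
    cfg = SceneConfig(
        n_targets=5,
        n_frames=30,
        frame_size=(320, 240),
        motion_model="constant_velocity",
        velocities=((3.0, 0.0),) * 5,
        clutter_rate=0.0,
        respawn=False,
        seed=5,
    )
    frames, gt = render_scene(cfg)
    dets = gt_as_detections(gt, confidence=0.95)
    return cfg, frames, gt, dets
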