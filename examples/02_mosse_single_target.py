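"""Follow one moving target with the raw MOSSE correlation filter.

Initialises the filter on the first ground-truth box, then propagates it
frame by frame with no further detector input, reporting the centroid
error against ground truth and the peak-to-sidelobe ratio (PSR) of each
correlation response.  PSR is the tracker's own confidence signal: it
collapses when the target is lost.
"""

import numpy as np

from fishtrack import SceneConfig, centroid, mosse_init, mosse_step, render_scene

scene = SceneConfig(
    n_targets=1,
    n_frames=50,
    motion_model="constant_velocity",
    velocities=((3.0, 0.0),),
    clutter_rate=0.0,
    respawn=False,
    seed=3,
)
frames, gt = render_scene(scene)
fish = next(iter(gt))
appearance = sorted(gt[fish])

state = mosse_init(frames[appearance[0]], gt[fish][appearance[0]], seed=0)
errors, psrs = [], []
for f in appearance[1:]:
    state, box, psr = mosse_step(state, frames[f])
    truth, estimate = centroid(gt[fish][f]), centroid(box)
    errors.append(np.hypot(truth.x - estimate.x, truth.y - estimate.y))
    psrs.append(psr)

print(f"tracked {len(errors)} frames at 3 px/frame")
print(f"mean centroid error: {np.mean(errors):.2f} px (max {np.max(errors):.2f})")
print(f"PSR: min {np.min(psrs):.1f}, mean {np.mean(psrs):.1f} (loss threshold 5.7)")
# a mean error well under the ~8 px target half-height means the filter
# stayed locked on the body; PSR far above 5.7 means it never came close
# to declaring the track lost
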