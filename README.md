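# fishtrack

Tracking-by-detection for fixed-camera underwater footage. Given per-frame
object-detector output (boxes + confidences) for fish swimming through a
camera's field of view, `fishtrack` assembles identity-preserving tracks,
quantifies each video's movement direction, and scores everything against
ground truth. It is aimed at ecologists running detector-based fish
monitoring — e.g. estuarine tidal corridors, where the question is "how
many fish, and which way were they moving?" — and at anyone who wants a
lightweight, fully inspectable multi-object tracking baseline with a
synthetic benchmark generator attached.

## What's inside

**Two tracker backends**, coupled to the detector through a handshake
protocol: a detection with confidence ≥ 0.80 spawns a track and
initialises the tracker; the tracker propagates the box on its own for 4
frames; on the next frame the tracker box is checked against fresh
detections — a detection overlapping it with IoU ≥ 0.30 re-anchors the
track, otherwise the track stops and unmatched detections spawn new
tracks.

* **MOSSE** (Minimum Output Sum of Squared Error), written from scratch on
  numpy FFTs. The filter `H` minimises the summed squared error between
  the correlation response and a Gaussian peak `G` over training patch
  spectra `F_i`:

      H* = Σᵢ G ⊙ F̄ᵢ / (Σᵢ Fᵢ ⊙ F̄ᵢ + ε)

  updated online by an exponential moving average (rate 0.125). Track
  quality is monitored with the peak-to-sidelobe ratio
  PSR = (peak − μ_sidelobe)/σ_sidelobe; PSR < 5.7 signals loss.
* **Seq-NMS-style detection linking**: detections in neighbouring frames
  are chained when their IoU ≥ 0.30 (greedy, one-to-one, highest IoU
  first). No tracker model — it needs a detection every frame, and a gap
  starts a new identity.

**Movement quantification**: frame-level displacement angles (compass
convention, 0° = up in the image, clockwise) binned into
up [315°,45°), right [45°,135°), down [135°,225°), left [225°,315°);
per-video counts, proportions, and *net movement* = argmax proportion.

**Evaluation**: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = their
harmonic mean; box-level AP50 (all-point interpolated area under the
precision–recall curve at IoU 0.5); individual-level tracking scoring —
a fish is a true positive when one track covers ≥ 50 % of its appearance
frames at IoU ≥ 0.5.

**Synthetic scenes**: fish-like blurred ellipses drifting through a
textured noisy frame under a tidal-drift or constant-velocity motion
model, with a configurable imperfect-detector simulator (miss rate,
false-positive rate, box jitter, confidence distributions). Every module
is testable end to end without any video download.

## Worked example

`python examples/01_track_synthetic_scene.py` renders a noise-free scene
of five fish drifting right at 3 px/frame, runs both backends, and scores
the tracks:

```
scene: 5 fish, 30 frames, 150 detections
mosse  : 5 tracks, tp=5 fp=0 fn=0, precision=1.00 recall=1.00
seqnms : 5 tracks, tp=5 fp=0 fn=0, precision=1.00 recall=1.00
```

Each fish is recovered as exactly one track with no identity mixing.
`examples/02_mosse_single_target.py` isolates the correlation filter
(mean centroid error 0.59 px over 49 frames, PSR ≥ 16.6);
`examples/03_movement_summary.py` recovers a simulated rightward tidal
flow as net movement `right` at proportion 0.94; and
`examples/04_evaluation_metrics.py` turns published individual-fish
confusion matrices into percentage metrics (e.g. detector
precision 95 % / recall 88 % / F1 91 %).

The same capabilities are exposed as a thin CLI —
`fishtrack synth | track | movement | evaluate` — which compose from one
YAML config; see `fishtrack --help`.

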