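# Methods

## The tracking-by-detection model

The package operationalises a detector-coupled tracking protocol for
fixed-camera footage. The detector is external: the pipeline consumes its
per-frame output (axis-aligned boxes, confidences in [0, 1]) and never
sees pixels except through the MOSSE backend. Detections below the
confidence threshold (default 0.80) are discarded up front; the threshold
is inclusive ("80 % or more confident").

A track's life cycle under the MOSSE backend: a surviving detection that
is not attributable to an existing track spawns a track and trains a
correlation filter on its box (frame *t*). The filter alone propagates
the box through frames *t*+1 … *t*+4 (`tracking_cycle_frames = 4`,
entries marked `source = tracker`). At frame *t*+5 the tracker box is
checked against that frame's detections: matching is greedy by descending
IoU, one-to-one, ties broken by track age then detection index, and the
overlap threshold (default IoU ≥ 0.30) is applied to the matched pair. A
passing match re-anchors the track on the detection box (a `detector`
entry) and starts a new cycle; a failing or missing match terminates the
track. Detections at a check frame not claimed by any checking track
spawn new tracks, so a fish whose track died is picked up again as a new
identity — the protocol deliberately favours continuity of *detection*
over continuity of *identity*. Between checks, a detection overlapping a
live track's current box is attributed to that track and spawns nothing.
Tracker failure between checks (PSR below threshold, or the box leaving
the frame entirely) also terminates the track. `check_grace` (default 0)
optionally lets a track coast through that many failed checks before
dying.

The Seq-NMS backend replaces propagation entirely: confidence-filtered
detections in neighbouring frames are chained when IoU ≥ 0.30, greedy
highest-IoU-first, one-to-one per frame pair, ties to the lower detection
index. A missed frame closes the chain — this linker assumes a detection
for every frame a fish is present. The rescoring and suppression parts of
the original sequential-NMS formulation are intentionally absent: only
the linking principle is used, and `run_pipeline` with this backend is a
type-level wrapper around `link_detections`.

The overlap measure for the MOSSE check is IoU. The protocol's "≥ 30 %
overlap" could also be read as fractional overlap of one box; IoU was
chosen for consistency with the linker, where intersection-over-union is
explicit. A SiamMask-style third backend is not implemented (it requires
trained network weights); its role in the protocol is structurally
identical to the MOSSE path.

## MOSSE internals

Filter mathematics follow the original minimum-output-sum-of-squared-
error formulation: with preprocessed patch spectra Fᵢ and a target
response G (2-D Gaussian, σ = 2 px), the filter is
conj(H) = A/B with A = Σ G⊙conj(Fᵢ), B = Σ Fᵢ⊙conj(Fᵢ), regularised by
ε = 1e−5 in the division. Preprocessing: log(1+I), zero mean, unit norm,
Hann window. Initialisation averages the unwarped patch with 8 small
random affine warps (rotation ≤ 10°, scale ± 5 %), all drawn from one
seeded generator, so runs are bit-reproducible. Online update is an EMA
with rate 0.125 (rate 1 degenerates to the newest single-frame filter,
which is tested). Displacement is the response-peak offset from the
window centre with quadratic sub-pixel refinement, wrap-aware; PSR
excludes an 11×11 window around the peak, and PSR < 5.7 flags loss.
Colour frames are collapsed with ITU-R 601 luma weights. All of these
are configuration fields, not constants.

One choice diverges from the minimal textbook setup: the correlation
window resamples a **search region of twice the target box**
(`patch_padding = 2.0`, box scaled about its centre) to the fixed 64×64
window, while output boxes keep the detection's width and height
(translation-only tracking; MOSSE does not estimate scale). With the
window equal to the box, a smooth fish-like body has its only
discriminative structure — its outline — under the tapering flank of the
Hann window, and measured displacements were biased toward zero by
roughly half, compounding into several pixels of lag per cycle. Padding
2.0 removes the bias (mean centroid error 0.6 px vs 5.4 px on the
constant-velocity benchmark scene) and roughly quadruples the PSR margin.
The cost is that a near neighbour can enter the search region sooner;
at the target densities used here that did not occur.

## Geometry and movement conventions

Boxes are 0-based `(x, y, w, h)` with half-open extent; converters at the
I/O boundary keep every other format aligned to this. Angles use the
compass convention forced by the direction-bin definitions: 0° = up in
the image (decreasing y), clockwise positive, i.e.
`atan2(dx, −dy) mod 360`. The four bins partition the circle as
half-open intervals (up [315°, 360°) ∪ [0°, 45°), right [45°, 135°),
down [135°, 225°), left [225°, 315°)); binning is verified exhaustively
against a literal interval oracle on all integer angles. Displacements
shorter than 0.5 px (configurable) yield no angle observation — the
direction of a null vector is meaningless, and sub-pixel jitter would
otherwise pollute the bins. Movement observations are **frame-level**
(one per consecutive-entry displacement, pooled over tracks), not
per-fish; proportions are over these observations, and net movement is
the argmax. Ties are reported as ties, never resolved silently, and a
net-movement comparison against a tied or empty summary returns
"incomparable" rather than a fabricated boolean. Camera-set orientation
is metadata only; directions are reported in the image frame.

## Evaluation

Frame-level detection matching is greedy one-to-one in descending
confidence at IoU ≥ 0.5. AP50 pools predictions across frames, ranks by
confidence, and integrates the all-point-interpolated precision–recall
curve; it is computed on **bounding boxes**. A mask-based detector
evaluation (as segmentation pipelines report) would differ; box IoU at
0.5 is the standard box-level analogue, and the implementation is checked
against an independent longhand PR-curve oracle on randomized small
instances to 1e−9.

Tracking is scored at the individual level: an individual is a true
positive when some single predicted track overlaps its boxes (IoU ≥ 0.5)
on at least 50 % of the frames in which it appears; below that it is a
false negative. A predicted track overlapping no individual on any frame
is a false positive. Track↔individual assignment is greedy by coverage
fraction, one-to-one, ties to the lower track id. This is an automated
surrogate for what is, in field studies, usually a manual per-second
judgement; the ≥ 50 %-coverage operationalisation is reproducible but
strict — fragmented tracking of a long-lived individual counts as a miss
even if every fragment is correct, because fragments cannot pool
coverage. That strictness is visible in the synthetic degradation sweep
(below).

Undefined metrics (0/0) are reported as absent values, never as zeros.

## The synthetic scene generator

The generator emulates the regime the pipeline targets: a fixed camera, a
handful of fish-sized objects (default 5 per 256×256 frame, semi-axes
14×8 px) moving at 2–4 px/frame, motion dominated by one horizontal
direction — each frame a target's heading follows
N(flow, 15°) with probability 0.9 (`drift_dominance`) and is uniform
otherwise — low-contrast texture, Gaussian pixel noise (σ = 4), sporadic
debris-like clutter blobs (0.2/frame), and targets entering and leaving
the field of view (an exited target is replaced by a new individual
entering upstream, as in a tidal corridor). Rendering (filled ellipses,
Gaussian-blurred, on a static smoothed-noise texture) is decoupled from
trajectory simulation so detector-only experiments skip rasterisation;
both consume independent child streams of one seed and yield identical
ground truth.

The detector simulator drops each true box with probability `miss_rate`,
jitters surviving corners (σ = 1 px), draws true confidences from
Beta(16, 2) — 88 % of mass above the 0.80 gate, so the gate rejects a
meaningful minority of true detections without gutting the signal — and
adds Poisson false positives (0.2/frame) with Beta(2, 4) confidences,
which the gate rejects > 99 % of the time.

What passing synthetic tests does *not* show: robustness to occlusion
(targets here rarely overlap), scale change, lighting drift, caustics, or
fish-like distractors. The generator is a correctness harness, not a
field benchmark; numbers on it upper-bound field performance.

## Problem sizes and observed behaviour

The standard test and acceptance workloads are deliberately small-scale:
the tracking benchmark is one target over 50 frames; end-to-end recovery
is 5 targets over 30 frames at 320×240; movement recovery is 10 seeded
80-frame scenes; the degradation sweep is 10 seeds × 4 miss rates of
detector-only scenes. On these, MOSSE's mean centroid error is ≈ 0.6 px,
both backends recover 5/5 individuals with precision = recall = 1, net
movement matches the simulated flow in 10/10 seeds, and mean tracking F1
falls monotonically (≈ 0.30 → 0 as miss rate goes 0 → 0.5). The modest
F1 even at miss rate 0 is the compound of the confidence gate (≈ 12 % of
true detections fall below 0.80) and the no-gap linker meeting the
single-track ≥ 50 %-coverage rule — an honest property of this
evaluation design, discussed above, not a defect of the sweep.

## Known limitations

Translation-only tracking (no scale/rotation adaptation); single-class
evaluation; no occlusion reasoning or re-identification — a fish that
leaves and re-enters is a new identity; the MOSSE backend's identity can
drift to a nearby fish if two bodies share a search region; movement
angles are 2-D image-frame angles, not water-frame headings (no
cross-camera triangulation).
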