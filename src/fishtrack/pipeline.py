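"""Detection-tracker interaction protocol over a whole video.

The protocol couples a per-frame object detector with a tracker:

1. A confidence-filtered detection spawns a track and initialises the
   tracker on its box.
2. The tracker propagates the box on its own for a fixed cycle of frames
   (default 4).
3. On the following frame the tracker box is checked against the fresh
   detections: a detection overlapping it by at least the overlap
   threshold (IoU >= 0.30 by default) re-anchors the track on that
   detection and a new cycle begins; otherwise the track terminates.
   Detections left unmatched at such a check frame spawn new tracks.

Two backends implement track propagation: ``mosse`` (the correlation
filter in :mod:`fishtrack.mosse`, needing the actual frames) and
``seqnms`` (pure detection linking via :mod:`fishtrack.seqnms`, needing a
detection on every frame the animal is present).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .detections import Detection, group_by_frame
from .geometry import BoundingBox, iou
from .mosse import MosseConfig, MosseState, mosse_init, mosse_step
from .seqnms import link_detections

__all__ = [
    "Source",
    "TrackEntry",
    "Track",
    "TrackerBackend",
    "PipelineConfig",
    "filter_detections",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class Source(str, Enum):
    DETECTOR = "detector"
    TRACKER = "tracker"


class TrackerBackend(str, Enum):
    MOSSE = "mosse"
    SEQNMS = "seqnms"


@dataclass(frozen=True)
class TrackEntry:
    frame_index: int
    box: BoundingBox
    source: Source


@dataclass
class Track:
    """An identity-bearing sequence of per-frame boxes.

    Tracks are born from detections: the first entry always has
    ``source = DETECTOR``.  ``terminated`` is False only for tracks still
    alive when the video ends.
    """

    track_id: int
    entries: list[TrackEntry] = field(default_factory=list)
    terminated: bool = False

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def frames(self) -> list[int]:
        return [e.frame_index for e in self.entries]

    def box_at(self, frame_index: int) -> BoundingBox | None:
        for e in self.entries:
            if e.frame_index == frame_index:
                return e.box
        return None


@dataclass(frozen=True)
class PipelineConfig:
    confidence_threshold: float = 0.80
    overlap_threshold: float = 0.30
    tracking_cycle_frames: int = 4
    tracker_backend: TrackerBackend = TrackerBackend.SEQNMS
    frame_rate: float = 25.0
    min_displacement: float = 0.5
    check_grace: int = 0  # failed checks tolerated before termination
    mosse: MosseConfig = field(default_factory=MosseConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must be in (0, 1]")
        if not (0.0 < self.overlap_threshold < 1.0):
            raise ValueError("overlap_threshold must be in (0, 1)")
        if self.tracking_cycle_frames < 1:
            raise ValueError("tracking_cycle_frames must be >= 1")


def filter_detections(
    detections: list[Detection], threshold: float = 0.80
) -> list[Detection]:
    """Keep detections with confidence >= threshold (inclusive), in order."""
    return [d for d in detections if d.confidence >= threshold]


@dataclass
class _LiveTrack:
    track: Track
    state: MosseState
    anchor_frame: int
    grace_allowance: int = 0
    misses: int = 0


def run_pipeline(
    frames: list[np.ndarray] | np.ndarray | None,
    detections: list[Detection] | dict[int, list[Detection]],
    config: PipelineConfig | None = None,
    n_frames: int | None = None,
    seed: int = 0,
) -> list[Track]:
    """Run the detect-track handshake over a video, returning all tracks.

    ``frames`` is an ordered sequence of image arrays; it is required for
    the MOSSE backend and ignored by the Seq-NMS backend.  ``detections``
    may be a flat list or a per-frame dict; they are confidence-filtered
    internally.  ``seed`` fixes the tracker-initialisation randomness, so
    identical inputs give bit-identical tracks.
    """
    cfg = config or PipelineConfig()
    flat = (
        [d for dets in detections.values() for d in dets]
        if isinstance(detections, dict)
        else list(detections)
    )
    flat = filter_detections(flat, cfg.confidence_threshold)
    if cfg.tracker_backend == TrackerBackend.SEQNMS:
        return _run_seqnms(flat, cfg)
    if frames is None:
        raise ValueError("the mosse backend requires the frame sequence")
    return _run_mosse(frames, flat, cfg, n_frames, seed)


def _run_seqnms(flat: list[Detection], cfg: PipelineConfig) -> list[Track]:
    chains = link_detections(flat, cfg.overlap_threshold)
    tracks = []
    for chain in chains:
        t = Track(track_id=chain.chain_id, terminated=True)
        t.entries = [
            TrackEntry(e.frame_index, e.box, Source.DETECTOR) for e in chain.entries
        ]
        tracks.append(t)
    return tracks


def _run_mosse(
    frames,
    flat: list[Detection],
    cfg: PipelineConfig,
    n_frames: int | None,
    seed: int,
) -> list[Track]:
    total = n_frames if n_frames is not None else len(frames)
    by_frame = group_by_frame(flat, total)
    tracks: list[Track] = []
    live: list[_LiveTrack] = []

    def spawn(det: Detection, t: int, frame) -> None:
        track = Track(track_id=len(tracks))
        track.entries.append(TrackEntry(t, det.box, Source.DETECTOR))
        tracks.append(track)
        state = mosse_init(frame, det.box, cfg.mosse, seed=(seed + track.track_id) % 2**31)
        live.append(
            _LiveTrack(
                track=track, state=state, anchor_frame=t, grace_allowance=cfg.check_grace
            )
        )
        logger.debug("frame %d: spawned track %d at %s", t, track.track_id, det.box.as_xywh())

    for t in range(total):
        frame = frames[t]
        dets = by_frame.get(t, [])

        # 1. propagate mid-cycle tracks through this frame
        for lt in list(live):
            if t <= lt.anchor_frame or t > lt.anchor_frame + cfg.tracking_cycle_frames:
                continue
            lt.state, box, psr = mosse_step(lt.state, frame)
            lt.track.entries.append(TrackEntry(t, box, Source.TRACKER))
            if lt.state.lost:
                lt.track.terminated = True
                live.remove(lt)
                logger.debug(
                    "frame %d: track %d lost (psr=%.2f)", t, lt.track.track_id, psr
                )

        # 2. check tracks due this frame against fresh detections
        checking = [
            lt
            for lt in live
            if t == lt.anchor_frame + cfg.tracking_cycle_frames + 1
        ]
        # greedy descending IoU, one-to-one; ties by track age then det index
        order = {id(lt): i for i, lt in enumerate(live)}
        candidates = []
        for lt in checking:
            tbox = lt.track.entries[-1].box
            for di, det in enumerate(dets):
                ov = iou(tbox, det.box)
                if ov > 0.0:
                    candidates.append((-ov, order[id(lt)], di, lt))
        candidates.sort(key=lambda c: c[:3])
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        for neg_ov, _, di, lt in candidates:
            if id(lt) in matched_tracks or di in matched_dets:
                continue
            matched_tracks.add(id(lt))
            matched_dets.add(di)
            if -neg_ov >= cfg.overlap_threshold:
                det = dets[di]
                lt.track.entries.append(TrackEntry(t, det.box, Source.DETECTOR))
                lt.state = mosse_init(
                    frame, det.box, cfg.mosse, seed=(seed + lt.track.track_id) % 2**31
                )
                lt.anchor_frame = t
                lt.misses = 0
                logger.debug("frame %d: track %d re-anchored", t, lt.track.track_id)
            else:
                matched_dets.discard(di)  # sub-threshold match fails the check
                _fail_check(lt, live, t)

        for lt in checking:
            if id(lt) not in matched_tracks:
                _fail_check(lt, live, t)

        # 3. unmatched detections spawn tracks unless attributable to a
        #    live mid-cycle track (same physical animal between checks)
        for di, det in enumerate(dets):
            if di in matched_dets:
                continue
            covered = any(
                iou(lt.track.entries[-1].box, det.box) >= cfg.overlap_threshold
                for lt in live
                if lt.anchor_frame != t
            )
            if not covered:
                spawn(det, t, frame)

    return tracks


def _fail_check(lt: _LiveTrack, live: list[_LiveTrack], t: int) -> None:
    lt.misses += 1
    if lt.misses > lt.grace_allowance:
        lt.track.terminated = True
        if lt in live:
            live.remove(lt)
        logger.debug("frame %d: track %d terminated at check", t, lt.track.track_id)
    else:
        lt.anchor_frame = t  # coast one more cycle from the current box
        logger.debug("frame %d: track %d coasting after failed check", t, lt.track.track_id)
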