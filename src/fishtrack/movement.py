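"""Movement-direction quantification from tracks.

Frame-level displacement angles are binned into four compass directions
(up / right / down / left) and aggregated per video: counts, proportions,
and *net movement* — the direction with the highest proportion of
observations.  The bins partition the circle as half-open intervals:

    up    [315, 360) u [0, 45)
    right [45, 135)
    down  [135, 225)
    left  [225, 315)

In fixed-camera footage of a tidal corridor, the horizontal bins (left /
right) carry the signal of interest: fish drifting with or against the
flow.  Camera-set orientation (e.g. a north-facing vs a south-facing rig)
is carried as metadata only; directions are reported in the image frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .geometry import centroid, displacement_angle
from .pipeline import Track

__all__ = [
    "Direction",
    "MovementSummary",
    "bin_direction",
    "track_directions",
    "summarize_video",
    "compare_net_movement",
]


class Direction(str, Enum):
    UP = "up"
    RIGHT = "right"
    DOWN = "down"
    LEFT = "left"


def bin_direction(angle: float) -> Direction:
    """Map a compass angle in [0, 360) to its direction bin."""
    if not (0.0 <= angle < 360.0):
        raise ValueError(f"angle {angle} outside [0, 360)")
    if angle < 45.0 or angle >= 315.0:
        return Direction.UP
    if angle < 135.0:
        return Direction.RIGHT
    if angle < 225.0:
        return Direction.DOWN
    return Direction.LEFT


@dataclass
class MovementSummary:
    """Per-video direction-bin counts, proportions, and net movement.

    ``net_movement`` is the direction with the highest proportion; when
    several directions tie for the maximum, or there are no observations,
    it is ``None`` and ``tie`` records whether a tie (rather than an empty
    video) caused it.
    """

    video_id: str
    camera_set: str
    counts: dict[Direction, int]
    proportions: dict[Direction, float]
    net_movement: Direction | None
    tie: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def track_directions(track: Track, min_displacement: float = 0.5) -> list[Direction]:
    """One direction observation per consecutive-entry displacement."""
    dirs: list[Direction] = []
    for prev, cur in zip(track.entries, track.entries[1:]):
        ang = displacement_angle(centroid(prev.box), centroid(cur.box), min_displacement)
        if ang is not None:
            dirs.append(bin_direction(ang))
    return dirs


def summarize_video(
    tracks: list[Track],
    video_id: str = "",
    camera_set: str = "",
    min_displacement: float = 0.5,
) -> MovementSummary:
    """Aggregate frame-level direction observations over a video's tracks."""
    counts = {d: 0 for d in Direction}
    for track in tracks:
        for d in track_directions(track, min_displacement):
            counts[d] += 1
    total = sum(counts.values())
    if total == 0:
        return MovementSummary(video_id, camera_set, counts, {d: 0.0 for d in Direction}, None)
    proportions = {d: counts[d] / total for d in Direction}
    best = max(proportions.values())
    winners = [d for d in Direction if proportions[d] == best]
    if len(winners) == 1:
        return MovementSummary(video_id, camera_set, counts, proportions, winners[0])
    return MovementSummary(video_id, camera_set, counts, proportions, None, tie=True)


def compare_net_movement(
    predicted: MovementSummary, ground_truth: MovementSummary
) -> bool | None:
    """True/False agreement of net directions; None when incomparable.

    Incomparable means either side has an undefined net movement (tie or
    no observations) — agreement must not be fabricated in that case.
    """
    if predicted.video_id != ground_truth.video_id:
        raise ValueError(
            f"video_id mismatch: {predicted.video_id!r} vs {ground_truth.video_id!r}"
        )
    if predicted.net_movement is None or ground_truth.net_movement is None:
        return None
    return predicted.net_movement == ground_truth.net_movement
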