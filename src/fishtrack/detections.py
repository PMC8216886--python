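"""Detection records: scored, class-labelled boxes on specific frames."""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import BoundingBox

__all__ = ["Detection", "group_by_frame"]


@dataclass(frozen=True)
class Detection:
    """A detector output: a box on one frame with a confidence score."""

    frame_index: int
    box: BoundingBox
    confidence: float = 1.0
    category_id: int = 1
    track_id: int | None = None  # ground-truth identity, when known

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


def group_by_frame(
    detections: list[Detection], n_frames: int | None = None
) -> dict[int, list[Detection]]:
    """Group a flat detection list into per-frame lists keyed by frame index.

    When ``n_frames`` is given, every frame in ``range(n_frames)`` gets an
    entry (possibly empty), which is what the frame-by-frame pipeline wants.
    """
    frames: dict[int, list[Detection]] = {}
    if n_frames is not None:
        frames = {t: [] for t in range(n_frames)}
    for det in detections:
        frames.setdefault(det.frame_index, []).append(det)
    return frames
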