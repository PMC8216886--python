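"""Detection linking across neighbouring frames by bounding-box overlap.

Chains per-frame detections into identity tracks: a detection in frame
``t+1`` joins the chain of the frame-``t`` detection it best overlaps when
that IoU clears the link threshold (default 0.30); otherwise it starts a
new chain, i.e. is treated as a new animal entering the scene.  Linking is
strictly between neighbouring frames — a missed detection terminates the
chain — so this tracker needs a detection in every frame the animal is
present.  Only the linking principle of Seq-NMS is used; the original
method's best-path rescoring and suppression are deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .detections import Detection, group_by_frame
from .geometry import BoundingBox, centroid, displacement_angle, iou

__all__ = ["ChainEntry", "DetectionChain", "link_detections", "chain_directions"]

DEFAULT_LINK_THRESHOLD = 0.30


@dataclass(frozen=True)
class ChainEntry:
    frame_index: int
    box: BoundingBox
    confidence: float


@dataclass
class DetectionChain:
    """A maximal run of IoU-linked detections on consecutive frames."""

    chain_id: int
    entries: list[ChainEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def last(self) -> ChainEntry:
        return self.entries[-1]


def link_detections(
    detections: list[Detection] | dict[int, list[Detection]],
    link_threshold: float = DEFAULT_LINK_THRESHOLD,
) -> list[DetectionChain]:
    """Partition detections into chains of IoU-linked neighbouring frames.

    Between each pair of consecutive frames, candidate (chain, detection)
    links are taken greedily in descending IoU order, one-to-one, keeping
    only links with IoU >= ``link_threshold``; IoU ties break toward the
    lower detection index.  Every detection ends up in exactly one chain.
    """
    if not (0.0 < link_threshold < 1.0):
        raise ValueError("link_threshold must be in (0, 1)")
    by_frame = (
        dict(detections)
        if isinstance(detections, dict)
        else group_by_frame(detections)
    )
    chains: list[DetectionChain] = []
    open_chains: dict[int, DetectionChain] = {}  # chains whose last entry is frame t-1

    for t in sorted(by_frame):
        dets = by_frame[t]
        if len({id(d) for d in dets}) != len(dets):
            raise ValueError(f"duplicate detection object in frame {t}")
        # a frame gap closes every chain: linking is neighbour-frame only
        open_chains = {
            ci: c for ci, c in open_chains.items() if c.last.frame_index == t - 1
        }
        candidates = []
        for ci, chain in open_chains.items():
            for di, det in enumerate(dets):
                ov = iou(chain.last.box, det.box)
                if ov >= link_threshold:
                    candidates.append((-ov, di, ci))
        candidates.sort()
        used_chains: set[int] = set()
        assigned: dict[int, int] = {}  # detection idx -> chain id
        for neg_ov, di, ci in candidates:
            if ci in used_chains or di in assigned:
                continue
            assigned[di] = ci
            used_chains.add(ci)

        next_open: dict[int, DetectionChain] = {}
        for di, det in enumerate(dets):
            if di in assigned:
                chain = open_chains[assigned[di]]
            else:
                chain = DetectionChain(chain_id=len(chains))
                chains.append(chain)
            chain.entries.append(ChainEntry(t, det.box, det.confidence))
            next_open[chain.chain_id] = chain
        open_chains = next_open

    return chains


def chain_directions(
    chain: DetectionChain, min_displacement: float = 0.5
) -> list[tuple[int, float]]:
    """Per-frame movement angles along a chain.

    One observation per consecutive entry pair, computed from centroid
    displacement under the compass convention; near-null displacements
    (below ``min_displacement`` px) are dropped.  Returns a list of
    ``(frame_index, angle_deg)`` where the frame index is that of the
    later entry of the pair.
    """
    out: list[tuple[int, float]] = []
    for prev, cur in zip(chain.entries, chain.entries[1:]):
        ang = displacement_angle(
            centroid(prev.box), centroid(cur.box), min_displacement
        )
        if ang is not None:
            out.append((cur.frame_index, ang))
    return out
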