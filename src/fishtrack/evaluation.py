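"""Detection and tracking evaluation: confusion counts, P/R/F1, AP50.

Three layers of assessment:

* frame-level detection matching (greedy one-to-one by confidence, IoU
  threshold 0.5) and the derived precision / recall / F1;
* average precision at IoU 0.5 (AP50) — area under the all-point
  interpolated precision-recall curve, predictions ranked by confidence;
* individual-level tracking scoring: a ground-truth individual counts as
  a true positive when some predicted track overlaps its boxes (IoU above
  threshold) on at least half of the frames in which it appears, as a
  false negative otherwise; a predicted track that never overlaps any
  individual counts as a false positive (a non-target object tracked).

AP is computed on bounding boxes.  A detector evaluated on segmentation
masks (as mask-based pipelines report) will score slightly differently;
box IoU at 0.5 is the standard box-level analogue.
"""

from __future__ import annotations

from dataclasses import dataclass

from .detections import Detection
from .geometry import BoundingBox, iou
from .pipeline import Track

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "compute_metrics",
    "match_detections",
    "average_precision_50",
    "score_tracking",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / FP / FN counts over a ground-truth population."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def ground_truth_total(self) -> int:
        return self.tp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Precision / recall / F1 (and optionally AP50); None = undefined.

    A metric is undefined (not zero) when its denominator vanishes:
    precision with no predictions, recall with no ground truth, F1 when
    precision + recall = 0.
    """

    precision: float | None
    recall: float | None
    f1: float | None
    map50: float | None = None


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Precision, recall and their harmonic mean from confusion counts."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricReport(precision=precision, recall=recall, f1=f1)


def _greedy_match_frame(
    gt: list[BoundingBox], preds: list[Detection], iou_threshold: float
) -> int:
    """Number of one-to-one matches; preds taken in descending confidence."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
    taken = [False] * len(gt)
    tp = 0
    for pi in order:
        best, best_ov = -1, iou_threshold
        for gi, g in enumerate(gt):
            if taken[gi]:
                continue
            ov = iou(preds[pi].box, g)
            if ov >= best_ov and (best == -1 or ov > best_ov):
                best, best_ov = gi, ov
        if best >= 0:
            taken[best] = True
            tp += 1
    return tp


def match_detections(
    gt_boxes: dict[int, list[BoundingBox]],
    pred: dict[int, list[Detection]],
    iou_threshold: float = 0.5,
) -> ConfusionCounts:
    """Frame-level confusion counts by greedy one-to-one box matching."""
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must be in (0, 1)")
    tp = fp = fn = 0
    for f in set(gt_boxes) | set(pred):
        g = gt_boxes.get(f, [])
        p = pred.get(f, [])
        m = _greedy_match_frame(g, p, iou_threshold)
        tp += m
        fp += len(p) - m
        fn += len(g) - m
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def average_precision_50(
    gt_boxes: dict[int, list[BoundingBox]],
    pred: dict[int, list[Detection]],
    iou_threshold: float = 0.5,
) -> float | None:
    """AP at the given IoU threshold, all-point interpolation, one class.

    Predictions are pooled across frames and ranked by descending
    confidence; each is matched greedily to the best still-unmatched
    ground-truth box of its frame.  Returns None when the ground truth is
    empty (the curve is undefined).
    """
    n_gt = sum(len(v) for v in gt_boxes.values())
    if n_gt == 0:
        return None
    pooled = [
        (d.confidence, f, i, d)
        for f, dets in pred.items()
        for i, d in enumerate(dets)
    ]
    if not pooled:
        return 0.0
    pooled.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken: dict[int, list[bool]] = {f: [False] * len(b) for f, b in gt_boxes.items()}
    flags: list[bool] = []
    for conf, f, _, det in pooled:
        gts = gt_boxes.get(f, [])
        best, best_ov = -1, iou_threshold
        for gi, g in enumerate(gts):
            if taken[f][gi]:
                continue
            ov = iou(det.box, g)
            if ov >= best_ov and (best == -1 or ov > best_ov):
                best, best_ov = gi, ov
        if best >= 0:
            taken[f][best] = True
            flags.append(True)
        else:
            flags.append(False)

    ap = 0.0
    tp = 0
    prev_recall = 0.0
    # all-point interpolation: precision at a recall level is the max
    # precision over that or any higher recall
    precisions = []
    recalls = []
    for k, is_tp in enumerate(flags, start=1):
        tp += is_tp
        precisions.append(tp / k)
        recalls.append(tp / n_gt)
    for i in range(len(precisions) - 2, -1, -1):
        precisions[i] = max(precisions[i], precisions[i + 1])
    for p, r in zip(precisions, recalls):
        ap += p * (r - prev_recall)
        prev_recall = r
    return ap


def _coverage(track: Track, frames: dict[int, BoundingBox], iou_threshold: float) -> float:
    """Fraction of an individual's appearance frames the track covers."""
    hit = 0
    for f, gbox in frames.items():
        tbox = track.box_at(f)
        if tbox is not None and iou(tbox, gbox) >= iou_threshold:
            hit += 1
    return hit / len(frames)


def score_tracking(
    gt_tracks: dict[int | str, dict[int, BoundingBox]],
    pred_tracks: list[Track],
    iou_threshold: float = 0.5,
    min_coverage: float = 0.5,
) -> ConfusionCounts:
    """Individual-level tracking confusion counts.

    ``gt_tracks`` maps each individual's id to its per-frame boxes.  Each
    predicted track may certify at most one individual and vice versa;
    the assignment is greedy by coverage fraction (ties: lower track id).
    An individual is TP when its assigned track covers >= ``min_coverage``
    of its appearance frames, else FN.  A predicted track overlapping no
    individual on any frame is FP.
    """
    cov: list[tuple[float, int, int | str]] = []
    overlaps_any = {t.track_id: False for t in pred_tracks}
    for track in pred_tracks:
        for gid, frames in gt_tracks.items():
            c = _coverage(track, frames, iou_threshold)
            if c > 0:
                overlaps_any[track.track_id] = True
                cov.append((-c, track.track_id, gid))
    cov.sort(key=lambda t: (t[0], t[1]))
    used_tracks: set[int] = set()
    certified: dict[int | str, float] = {}
    for neg_c, tid, gid in cov:
        if tid in used_tracks or gid in certified:
            continue
        used_tracks.add(tid)
        certified[gid] = -neg_c

    tp = sum(1 for gid, c in certified.items() if c >= min_coverage)
    fn = len(gt_tracks) - tp
    fp = sum(1 for t in pred_tracks if not overlaps_any[t.track_id])
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)
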