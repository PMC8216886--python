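import numpy as np
import pytest

from fishtrack.detections import Detection
from fishtrack.evaluation import (
    ConfusionCounts,
    average_precision_50,
    compute_metrics,
    match_detections,
    score_tracking,
)
from fishtrack.geometry import BoundingBox, iou
from fishtrack.pipeline import Source, Track, TrackEntry


def ap_oracle(gt_boxes, pred, iou_threshold=0.5):
    """Independent all-point AP: explicit PR points, max-right scan.

    Matching follows the same published rule (confidence-ranked greedy,
    best IoU), but the curve handling is written out longhand: one
    (precision, recall) point per prediction prefix, interpolated
    precision at each recall level found by scanning all points at or
    beyond that recall.
    """
    n_gt = sum(len(v) for v in gt_boxes.values())
    ranked = sorted(
        ((d, f) for f, dets in pred.items() for d in dets),
        key=lambda t: -t[0].confidence,
    )
    taken = {f: set() for f in gt_boxes}
    points = []
    tp = 0
    for k, (d, f) in enumerate(ranked, start=1):
        cands = [
            (iou(d.box, g), gi)
            for gi, g in enumerate(gt_boxes.get(f, []))
            if gi not in taken.get(f, set())
        ]
        cands = [c for c in cands if c[0] >= iou_threshold]
        if cands:
            best = max(cands)
            taken[f].add(best[1])
            tp += 1
        points.append((tp / k, tp / n_gt))
    ap = 0.0
    prev_r = 0.0
    for p, r in points:
        if r > prev_r:
            p_interp = max(pp for pp, rr in points if rr >= r)
            ap += p_interp * (r - prev_r)
            prev_r = r
    return ap


class TestComputeMetrics:
    # confusion rows: (tp, fp, fn) -> printed integer percentages
    WORKED_EXAMPLES = [
        ((148, 8, 21), (95, 88, 91)),  # single-class detector
        ((123, 23, 46), (84, 73, 78)),  # correlation-filter tracking
        ((129, 9, 40), (93, 76, 84)),  # detection linking
        ((121, 19, 48), (86, 72, 78)),  # siamese tracking
    ]

    @pytest.mark.parametrize("counts, expected", WORKED_EXAMPLES)
    def test_reproduces_printed_percentages(self, counts, expected):
        tp, fp, fn = counts
        r = compute_metrics(ConfusionCounts(tp, fp, fn))
        assert (
            round(r.precision * 100),
            round(r.recall * 100),
            round(r.f1 * 100),
        ) == expected

    def test_degenerate_cases_are_undefined_not_zero(self):
        r = compute_metrics(ConfusionCounts(tp=0, fp=5, fn=5))
        assert r.precision == 0.0 and r.recall == 0.0 and r.f1 is None
        r = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=5))
        assert r.precision is None and r.recall == 0.0
        r = compute_metrics(ConfusionCounts(tp=0, fp=5, fn=0))
        assert r.recall is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)


class TestMatchDetections:
    def test_perfect_predictions(self):
        gt = {0: [BoundingBox(0, 0, 10, 10)], 1: [BoundingBox(5, 5, 8, 8)]}
        pred = {f: [Detection(f, b, 1.0) for b in boxes] for f, boxes in gt.items()}
        c = match_detections(gt, pred)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_no_predictions(self):
        gt = {0: [BoundingBox(0, 0, 10, 10)] * 3}
        c = match_detections(gt, {})
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)

    def test_one_to_one_rule(self):
        gt = {0: [BoundingBox(0, 0, 10, 10)]}
        pred = {
            0: [
                Detection(0, BoundingBox(0, 0, 10, 10), 0.9),
                Detection(0, BoundingBox(1, 0, 10, 10), 0.8),
            ]
        }
        c = match_detections(gt, pred)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        gt = {0: [BoundingBox(*rng.uniform(0, 50, 2), *rng.uniform(5, 20, 2)) for _ in range(4)]}
        pred = {
            0: [
                Detection(0, BoundingBox(b.x + 1, b.y - 1, b.w, b.h), 0.9)
                for b in gt[0][:3]
            ]
        }

        def scaled(factor):
            g = {0: [BoundingBox(b.x * factor, b.y * factor, b.w * factor, b.h * factor) for b in gt[0]]}
            p = {
                0: [
                    Detection(0, BoundingBox(d.box.x * factor, d.box.y * factor,
                                             d.box.w * factor, d.box.h * factor), d.confidence)
                    for d in pred[0]
                ]
            }
            return match_detections(g, p)

        assert scaled(1.0) == scaled(7.5)


class TestAveragePrecision:
    def test_perfect_predictions_score_one(self):
        gt = {0: [BoundingBox(0, 0, 10, 10), BoundingBox(40, 40, 10, 10)]}
        pred = {0: [Detection(0, b, 1.0) for b in gt[0]]}
        assert average_precision_50(gt, pred) == pytest.approx(1.0)

    def test_no_predictions_scores_zero(self):
        gt = {0: [BoundingBox(0, 0, 10, 10)]}
        assert average_precision_50(gt, {}) == 0.0

    def test_empty_ground_truth_undefined(self):
        assert average_precision_50({}, {0: []}) is None

    def test_half_matched_example(self):
        gt = {0: [BoundingBox(0, 0, 10, 10), BoundingBox(50, 50, 10, 10)]}
        pred = {
            0: [
                Detection(0, BoundingBox(0, 0, 10, 10), 0.9),
                Detection(0, BoundingBox(200, 200, 5, 5), 0.8),
            ]
        }
        assert average_precision_50(gt, pred) == pytest.approx(0.5)

    def test_agrees_with_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for trial in range(60):
            n_gt = int(rng.integers(1, 6))
            n_pred = int(rng.integers(0, 7))
            gt = {
                0: [
                    BoundingBox(*rng.uniform(0, 40, 2), *rng.uniform(5, 15, 2))
                    for _ in range(n_gt)
                ]
            }
            pred = {
                0: [
                    Detection(
                        0,
                        BoundingBox(*rng.uniform(0, 40, 2), *rng.uniform(5, 15, 2)),
                        float(rng.uniform(0.1, 1.0)),
                    )
                    for _ in range(n_pred)
                ]
            }
            got = average_precision_50(gt, pred)
            expected = ap_oracle(gt, pred)
            assert got == pytest.approx(expected, abs=1e-9)


def make_track(tid, boxes_by_frame):
    t = Track(track_id=tid, terminated=True)
    for f in sorted(boxes_by_frame):
        t.entries.append(TrackEntry(f, boxes_by_frame[f], Source.DETECTOR))
    return t


class TestScoreTracking:
    def _individual(self, frames, x0=10.0, y0=10.0, vx=3.0):
        return {f: BoundingBox(x0 + vx * i, y0, 12, 8) for i, f in enumerate(frames)}

    def test_coverage_above_half_is_tp(self):
        ind = self._individual(range(10))
        track = make_track(0, {f: ind[f] for f in range(6)})  # 6 of 10 frames
        c = score_tracking({"fish": ind}, [track])
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_coverage_below_half_is_fn(self):
        ind = self._individual(range(10))
        track = make_track(0, {f: ind[f] for f in range(4)})  # 4 of 10 frames
        c = score_tracking({"fish": ind}, [track])
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_track_with_no_overlap_is_fp(self):
        ind = self._individual(range(10))
        stray = make_track(1, {f: BoundingBox(200, 200, 10, 10) for f in range(5)})
        c = score_tracking({"fish": ind}, [stray])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_one_track_certifies_at_most_one_individual(self):
        a = self._individual(range(10), y0=10)
        b = {f: box for f, box in self._individual(range(10), y0=10).items()}
        # two identical individuals; a single track can certify only one
        track = make_track(0, dict(a))
        c = score_tracking({"a": a, "b": b}, [track])
        assert c.tp == 1 and c.fn == 1

    def test_perfect_tracking_no_errors(self):
        inds = {
            i: self._individual(range(8), y0=10 + 30 * i) for i in range(3)
        }
        tracks = [make_track(i, dict(ind)) for i, ind in inds.items()]
        c = score_tracking(inds, tracks)
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)
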