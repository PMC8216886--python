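"""Readers and writers for the on-disk formats.

* detections / ground truth: COCO-style JSON — ``images`` with
  ``frame_index``, ``annotations`` with 0-based ``bbox`` ``[x, y, w, h]``,
  ``score``, ``category_id`` and (for ground truth) ``track_id``;
* tracks: MOT-challenge-style CSV with one row per track per frame;
* movement summaries: flat CSV;
* metric reports: JSON;
* frames: an ordered directory of PNG images (video containers are out of
  scope; fixed-camera footage is assumed pre-exploded into still frames).

All coordinate conversions happen here; in memory everything is the
0-based ``(x, y, w, h)`` convention of :mod:`fishtrack.geometry`.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .detections import Detection, group_by_frame
from .evaluation import MetricReport
from .geometry import BoundingBox
from .movement import Direction, MovementSummary
from .pipeline import PipelineConfig, Source, Track, TrackEntry, TrackerBackend
from .synthetic import DetectorNoiseConfig, GroundTruth, SceneConfig

__all__ = [
    "ParseError",
    "read_detections",
    "write_detections",
    "read_ground_truth",
    "write_ground_truth",
    "read_tracks",
    "write_tracks",
    "write_movement_summaries",
    "write_metrics",
    "read_frames",
    "write_frames",
    "load_configs",
]

TRACK_COLUMNS = ["frame", "track_id", "x", "y", "w", "h", "confidence", "source"]


class ParseError(ValueError):
    """A file did not conform to the expected dialect."""


def _parse_annotation(ann: dict, frame_of: dict) -> Detection:
    try:
        bbox = ann["bbox"]
        if len(bbox) != 4:
            raise ParseError(f"annotation {ann.get('id')}: bbox must have 4 entries")
        x, y, w, h = (float(v) for v in bbox)
        if w <= 0 or h <= 0:
            raise ParseError(
                f"annotation {ann.get('id')}: degenerate bbox w={w}, h={h}"
            )
        image_id = ann["image_id"]
        if image_id not in frame_of:
            raise ParseError(f"annotation {ann.get('id')}: unknown image_id {image_id}")
        return Detection(
            frame_index=frame_of[image_id],
            box=BoundingBox(x, y, w, h),
            confidence=float(ann.get("score", 1.0)),
            category_id=int(ann.get("category_id", 1)),
            track_id=ann.get("track_id"),
        )
    except KeyError as e:
        raise ParseError(f"annotation {ann.get('id')}: missing field {e}") from e


def read_detections(path: str | Path) -> dict[int, list[Detection]]:
    """Read a COCO-style detection/ground-truth JSON into per-frame lists.

    Every image listed gets an entry (possibly empty), so frames with no
    detections are represented explicitly.
    """
    with open(path) as f:
        try:
            doc = json.load(f)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: not valid JSON ({e})") from e
    try:
        images = doc["images"]
    except KeyError as e:
        raise ParseError(f"{path}: missing top-level 'images'") from e
    frame_of = {}
    for img in images:
        try:
            frame_of[img["id"]] = int(img["frame_index"])
        except KeyError as e:
            raise ParseError(f"{path}: image {img.get('id')}: missing {e}") from e
    if len(set(frame_of.values())) != len(frame_of):
        raise ParseError(f"{path}: duplicate frame_index among images")
    out: dict[int, list[Detection]] = {fi: [] for fi in frame_of.values()}
    for ann in doc.get("annotations", []):
        det = _parse_annotation(ann, frame_of)
        out[det.frame_index].append(det)
    return out


def write_detections(detections: dict[int, list[Detection]], path: str | Path) -> None:
    """Write per-frame detections as COCO-style JSON (round-trip safe)."""
    images = [
        {"id": fi, "file_name": f"frame_{fi:06d}.png", "frame_index": fi}
        for fi in sorted(detections)
    ]
    annotations = []
    for fi in sorted(detections):
        for det in detections[fi]:
            ann = {
                "id": len(annotations),
                "image_id": fi,
                "bbox": list(det.box.as_xywh()),
                "score": det.confidence,
                "category_id": det.category_id,
            }
            if det.track_id is not None:
                ann["track_id"] = det.track_id
            annotations.append(ann)
    with open(path, "w") as f:
        json.dump({"images": images, "annotations": annotations}, f, indent=1)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write per-individual ground truth as COCO-style JSON with track ids."""
    per_frame: dict[int, list[Detection]] = {}
    for tid in sorted(gt):
        for fi, box in sorted(gt[tid].items()):
            per_frame.setdefault(fi, []).append(
                Detection(fi, box, confidence=1.0, track_id=tid)
            )
    write_detections(per_frame, path)


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a ground-truth JSON (annotations must carry track_id)."""
    per_frame = read_detections(path)
    gt: GroundTruth = {}
    for fi, dets in per_frame.items():
        for det in dets:
            if det.track_id is None:
                raise ParseError(f"{path}: frame {fi}: annotation lacks track_id")
            gt.setdefault(det.track_id, {})[fi] = det.box
    return gt


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write tracks as MOT-style CSV, sorted by (frame, track_id)."""
    rows = [
        (e.frame_index, t.track_id, e.box.x, e.box.y, e.box.w, e.box.h, 1.0, e.source.value)
        for t in tracks
        for e in t.entries
    ]
    rows.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    # 17 significant digits: exact float64 round-trip through text
    df.to_csv(path, index=False, float_format="%.17g")


def read_tracks(path: str | Path) -> list[Track]:
    """Read a MOT-style track CSV back into Track objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    tracks: dict[int, Track] = {}
    for row in df.sort_values(["track_id", "frame"]).itertuples(index=False):
        tid = int(row.track_id)
        track = tracks.setdefault(tid, Track(track_id=tid, terminated=True))
        track.entries.append(
            TrackEntry(
                int(row.frame),
                BoundingBox(float(row.x), float(row.y), float(row.w), float(row.h)),
                Source(row.source),
            )
        )
    return [tracks[tid] for tid in sorted(tracks)]


def write_movement_summaries(summaries: list[MovementSummary], path: str | Path) -> None:
    rows = []
    for s in summaries:
        row = {"video_id": s.video_id, "camera_set": s.camera_set}
        for d in Direction:
            row[f"n_{d.value}"] = s.counts[d]
        for d in Direction:
            row[f"p_{d.value}"] = s.proportions[d]
        row["net"] = "tie" if s.tie else (s.net_movement.value if s.net_movement else "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metrics(report: MetricReport, path: str | Path, extra: dict | None = None) -> None:
    doc = {
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "map50": report.map50,
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as f:
        json.dump(doc, f, indent=1)


def write_frames(frames: np.ndarray, out_dir: str | Path) -> list[Path]:
    """Write a (T, H, W) float array as numbered 8-bit PNGs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"frame_{i:06d}.png"
        iio.imwrite(p, np.round(np.clip(frame, 0, 255)).astype(np.uint8))
        paths.append(p)
    return paths


def read_frames(frames_dir: str | Path) -> np.ndarray:
    """Read an ordered PNG/JPEG frame directory into a (T, H, W[, C]) array."""
    paths = sorted(
        p
        for p in Path(frames_dir).iterdir()
        if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not paths:
        raise ParseError(f"{frames_dir}: no image frames found")
    return np.stack([np.asarray(iio.imread(p), dtype=np.float64) for p in paths])


def load_configs(
    path: str | Path,
) -> tuple[SceneConfig, DetectorNoiseConfig, PipelineConfig]:
    """Load scene / detector-noise / pipeline configs from one YAML file.

    Top-level keys ``scene``, ``detector_noise`` and ``pipeline`` are each
    optional; omitted sections take the package defaults.
    """
    with open(path) as f:
        doc = yaml.safe_load(f) or {}
    scene_kw = dict(doc.get("scene", {}))
    for key in ("frame_size", "speed_range", "target_axes"):
        if key in scene_kw:
            scene_kw[key] = tuple(scene_kw[key])
    pipe_kw = dict(doc.get("pipeline", {}))
    if "tracker_backend" in pipe_kw:
        pipe_kw["tracker_backend"] = TrackerBackend(pipe_kw["tracker_backend"])
    noise_kw = dict(doc.get("detector_noise", {}))
    for key in ("true_conf_beta", "false_conf_beta"):
        if key in noise_kw:
            noise_kw[key] = tuple(noise_kw[key])
    return (
        SceneConfig(**scene_kw),
        DetectorNoiseConfig(**noise_kw),
        PipelineConfig(**pipe_kw),
    )
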