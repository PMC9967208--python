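"""File formats: COCO-style detection results, ground-truth tracks, scorer
coefficients and YAML configuration.

Detections travel in a COCO-results dialect: a list of
``{image_id, category_id, bbox: [x, y, w, h], score}`` records plus a
sidecar image list mapping ``image_id`` to a frame number — necessary
because an endoscopy stream is an ordered frame sequence, not an unordered
image collection.  Optional fields ``cc`` (class-confidence vector) and
``embedding`` round-trip losslessly when present.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .core import BoundingBox, Detection, GroundTruthTrack, VideoPredictions
from .errors import ConfigError, SchemaError
from .refinement import ReppConfig
from .simulate import SimulationConfig

__all__ = [
    "read_detections",
    "write_detections",
    "read_ground_truth",
    "write_ground_truth",
    "load_config",
    "repp_config_from_dict",
    "simulation_config_from_dict",
]

PathLike = Union[str, Path]


def _require(record: dict, key: str, where: str):
    if key not in record:
        raise SchemaError(f"{where}: missing required key {key!r}")
    return record[key]


def write_detections(video: VideoPredictions, path: PathLike) -> None:
    """Write a video's detections as COCO-style results JSON."""
    images = [{"id": t, "frame": t} for t in range(video.n_frames)]
    annotations = []
    for t, dets in enumerate(video.frames):
        for d in dets:
            rec = {
                "image_id": t,
                "category_id": 1,
                "bbox": d.box.to_xywh(),
                "score": d.score,
                "cc": [float(v) for v in d.cc],
                "objectness": d.objectness,
            }
            if d.app is not None:
                rec["embedding"] = [float(v) for v in d.app]
            annotations.append(rec)
    payload = {
        "video": {
            "width": video.frame_width,
            "height": video.frame_height,
            "fps": video.fps,
            "n_frames": video.n_frames,
        },
        "images": images,
        "annotations": annotations,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def read_detections(path: PathLike) -> VideoPredictions:
    """Read a detections file written by :func:`write_detections`.

    Schema violations raise :class:`SchemaError` naming the offending record.
    """
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as e:
            raise SchemaError(f"{path}: malformed JSON: {e}") from e
    meta = _require(payload, "video", str(path))
    images = _require(payload, "images", str(path))
    frame_of = {}
    for k, im in enumerate(images):
        frame_of[_require(im, "id", f"images[{k}]")] = _require(im, "frame", f"images[{k}]")
    n_frames = int(meta.get("n_frames", len(images)))
    if n_frames < 1:
        raise SchemaError(f"{path}: video must declare at least one frame")
    frames: list[list[Detection]] = [[] for _ in range(n_frames)]
    for k, rec in enumerate(_require(payload, "annotations", str(path))):
        where = f"annotations[{k}]"
        image_id = _require(rec, "image_id", where)
        if image_id not in frame_of:
            raise SchemaError(f"{where}: image_id {image_id!r} not in image map")
        frame = int(frame_of[image_id])
        bbox = _require(rec, "bbox", where)
        if len(bbox) != 4:
            raise SchemaError(f"{where}: bbox must have 4 entries")
        if bbox[2] <= 0 or bbox[3] <= 0:
            raise SchemaError(f"{where}: non-positive box extent {bbox[2]}x{bbox[3]}")
        cc = rec.get("cc", [ _require(rec, "score", where) ])
        app = rec.get("embedding")
        try:
            det = Detection(
                frame=frame,
                box=BoundingBox(*[float(v) for v in bbox]),
                cc=np.asarray(cc, dtype=float),
                objectness=float(rec.get("objectness", 1.0)),
                app=None if app is None else np.asarray(app, dtype=float),
            )
        except ValueError as e:
            raise SchemaError(f"{where}: {e}") from e
        if not 0 <= frame < n_frames:
            raise SchemaError(f"{where}: frame {frame} outside [0, {n_frames})")
        frames[frame].append(det)
    return VideoPredictions(
        frames,
        float(_require(meta, "width", "video")),
        float(_require(meta, "height", "video")),
        float(_require(meta, "fps", "video")),
    )


def write_ground_truth(
    tracks: list[GroundTruthTrack],
    path: PathLike,
    width: float,
    height: float,
    fps: float,
    n_frames: int,
) -> None:
    """Write annotated tracks and video metadata as JSON."""
    payload = {
        "video": {"width": width, "height": height, "fps": fps, "n_frames": n_frames},
        "tracks": [
            {
                "id": t.track_id,
                "first_frame": t.first_frame,
                "boxes": {str(f): b.to_xywh() for f, b in sorted(t.boxes.items())},
            }
            for t in tracks
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def read_ground_truth(path: PathLike) -> tuple[list[GroundTruthTrack], dict]:
    """Read ground truth; returns (tracks, video-metadata dict)."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as e:
            raise SchemaError(f"{path}: malformed JSON: {e}") from e
    meta = _require(payload, "video", str(path))
    tracks = []
    for k, rec in enumerate(_require(payload, "tracks", str(path))):
        where = f"tracks[{k}]"
        boxes_raw = _require(rec, "boxes", where)
        if not boxes_raw:
            raise SchemaError(f"{where}: track has no boxes")
        boxes = {}
        for f_str, bbox in boxes_raw.items():
            if len(bbox) != 4 or bbox[2] <= 0 or bbox[3] <= 0:
                raise SchemaError(f"{where}: invalid box at frame {f_str}")
            boxes[int(f_str)] = BoundingBox(*[float(v) for v in bbox])
        track = GroundTruthTrack(track_id=_require(rec, "id", where), boxes=boxes)
        declared = rec.get("first_frame")
        if declared is not None and int(declared) != track.first_frame:
            raise SchemaError(
                f"{where}: first_frame {declared} inconsistent with boxes "
                f"(min annotated frame is {track.first_frame})"
            )
        tracks.append(track)
    return tracks, dict(meta)


def _from_dict(cls, d: dict, what: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"unknown {what} keys: {sorted(unknown)}")
    return cls(**d)


def repp_config_from_dict(d: dict) -> ReppConfig:
    return _from_dict(ReppConfig, d, "refinement config")


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    return _from_dict(SimulationConfig, d, "simulation config")


def load_config(path: PathLike) -> dict:
    """Load a YAML config file as a plain dict (empty file -> empty dict)."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise ConfigError(f"{path}: malformed YAML: {e}") from e
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return data
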