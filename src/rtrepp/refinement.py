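"""Tubelet refinement: rescoring, coordinate smoothing, batch post-processing
and the real-time sliding-window variant.

The batch pipeline (``repp``) runs, in order: prefilter low-confidence
detections, link detections into tubelets, replace every confidence vector by
its tubelet mean, optionally smooth the box-coordinate time series with a 1-D
Gaussian, drop unmatched (singleton) tubelets, drop tubelets whose rescored
confidence falls below the final threshold, and flatten tubelets back to
per-frame detection lists.

The streaming variant (``RtReppStream``) keeps a ring buffer of the ``ws``
most recent raw frames.  Each pushed frame evicts the oldest once the buffer
is full, the batch pipeline runs on the buffer contents, and only the newest
frame's refined detections are emitted.  During warm-up the pipeline runs on
the partial buffer from the first frame onward, so output at frame t always
equals the batch result on the trailing window restricted to frame t.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import BoundingBox, Detection, Tubelet, VideoPredictions
from .errors import ConfigError
from .linking import (
    DEFAULT_LINK_THRESHOLD,
    LinkScorer,
    build_tubelets,
    get_pairs,
    tubelet_members,
)

__all__ = [
    "ReppConfig",
    "rescore_tubelets",
    "recoordinate_tubelets",
    "tubelets_to_predictions",
    "repp",
    "repp_survivors",
    "RtReppStream",
    "rt_repp_replay",
]


@dataclass
class ReppConfig:
    """Tunable parameters of the post-processing pipeline.

    Attributes
    ----------
    window_size
        Sliding-buffer capacity in frames for the real-time variant.  300
        frames cover 12 s at 25 fps; larger buffers no longer change results
        appreciably while costing proportionally more per frame.
    linking_threshold
        Minimum link score for two consecutive-frame detections to pair.
    prefilter_confidence
        Detections below this confidence are removed before linking.
    recoordinate
        Whether to smooth box-coordinate time series.
    smoothing_sigma
        Standard deviation, in frames, of the Gaussian smoothing kernel.
    drop_unmatched
        Drop tubelets of length 1 (detections that linked to nothing).
    final_score_threshold
        Detections whose rescored confidence falls below this are discarded.
    """

    window_size: int = 300
    linking_threshold: float = DEFAULT_LINK_THRESHOLD
    prefilter_confidence: float = 0.01
    recoordinate: bool = True
    smoothing_sigma: float = 1.5
    drop_unmatched: bool = True
    final_score_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ConfigError("window_size must be >= 1")
        for name in ("linking_threshold", "prefilter_confidence", "final_score_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.smoothing_sigma <= 0:
            raise ConfigError("smoothing_sigma must be positive")


def rescore_tubelets(tubelets: Iterable[Tubelet]) -> list[Tubelet]:
    """Replace each detection's class-confidence vector by the tubelet mean.

    Averaging corrects isolated low-confidence or mislabeled detections
    using the rest of the track; it is idempotent and conserves the sum of
    confidences within each tubelet.
    """
    out = []
    for t in tubelets:
        mean_cc = np.mean([d.cc for d in t.detections], axis=0)
        dets = [replace(d, cc=mean_cc.copy()) for d in t.detections]
        out.append(Tubelet(start_frame=t.start_frame, detections=dets, id=t.id))
    return out


def _smooth(series: np.ndarray, sigma: float) -> np.ndarray:
    # reflective (half-sample symmetric) boundary; truncation at 4 sigma
    return gaussian_filter1d(series, sigma, mode="reflect", truncate=4.0)


def recoordinate_tubelets(tubelets: Iterable[Tubelet], sigma: float = 1.5) -> list[Tubelet]:
    """Smooth each tubelet's box trajectory with a 1-D Gaussian filter.

    The four series smoothed are center-x, center-y, width and height — the
    same position/geometry decomposition the link features use — each
    convolved with a normalized Gaussian kernel under a reflective boundary,
    then reassembled into boxes.  Constant trajectories are unchanged; a
    sigma small enough that the truncated kernel has zero radius reduces to
    the identity.
    """
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    out = []
    for t in tubelets:
        boxes = [d.box for d in t.detections]
        cx = np.array([b.x + b.w / 2 for b in boxes], dtype=float)
        cy = np.array([b.y + b.h / 2 for b in boxes], dtype=float)
        w = np.array([b.w for b in boxes], dtype=float)
        h = np.array([b.h for b in boxes], dtype=float)
        cx, cy, w, h = (_smooth(s, sigma) for s in (cx, cy, w, h))
        dets = [
            replace(
                d,
                box=BoundingBox(
                    x=cx[k] - w[k] / 2, y=cy[k] - h[k] / 2, w=w[k], h=h[k]
                ),
            )
            for k, d in enumerate(t.detections)
        ]
        out.append(Tubelet(start_frame=t.start_frame, detections=dets, id=t.id))
    return out


def tubelets_to_predictions(
    tubelets: Iterable[Tubelet], template: VideoPredictions
) -> VideoPredictions:
    """Flatten tubelets back into per-frame detection lists shaped like
    ``template`` (same frame count, dimensions and fps)."""
    frames: list[list[Detection]] = [[] for _ in range(template.n_frames)]
    for t in sorted(tubelets, key=lambda t: t.id):
        for d in t.detections:
            frames[d.frame].append(d)
    return VideoPredictions(
        frames, template.frame_width, template.frame_height, template.fps
    )


def repp(
    video: VideoPredictions,
    scorer: Optional[LinkScorer] = None,
    cfg: Optional[ReppConfig] = None,
) -> VideoPredictions:
    """Batch post-processing of a full video's detections.

    Returns a new ``VideoPredictions`` with the same frame count; every
    output detection corresponds to an input detection of the same frame,
    possibly with an adjusted box and rescored confidence.
    """
    scorer = scorer if scorer is not None else LinkScorer.default()
    cfg = cfg if cfg is not None else ReppConfig()
    filtered = VideoPredictions(
        [
            [d for d in dets if d.score >= cfg.prefilter_confidence]
            for dets in video.frames
        ],
        video.frame_width,
        video.frame_height,
        video.fps,
    )
    pairs = get_pairs(filtered, scorer, cfg.linking_threshold)
    tubelets = build_tubelets(filtered, pairs)
    tubelets = rescore_tubelets(tubelets)
    if cfg.recoordinate:
        tubelets = recoordinate_tubelets(tubelets, cfg.smoothing_sigma)
    if cfg.drop_unmatched:
        tubelets = [t for t in tubelets if len(t) > 1]
    tubelets = [
        t for t in tubelets if t.detections[0].score >= cfg.final_score_threshold
    ]
    return tubelets_to_predictions(tubelets, video)


def repp_survivors(
    video: VideoPredictions,
    scorer: Optional[LinkScorer] = None,
    cfg: Optional[ReppConfig] = None,
) -> list[set[int]]:
    """Which input detections the batch pipeline retains.

    Returns, per frame, the set of indices into ``video.frames[t]`` whose
    detection survives prefiltering, singleton dropping and the final
    rescored-confidence threshold.  Useful for provenance audits: the boxes
    and scores of survivors may still change, but membership is decided here.
    """
    scorer = scorer if scorer is not None else LinkScorer.default()
    cfg = cfg if cfg is not None else ReppConfig()
    keep_map: list[list[int]] = [
        [i for i, d in enumerate(dets) if d.score >= cfg.prefilter_confidence]
        for dets in video.frames
    ]
    filtered = VideoPredictions(
        [[video.frames[t][i] for i in keep] for t, keep in enumerate(keep_map)],
        video.frame_width,
        video.frame_height,
        video.fps,
    )
    pairs = get_pairs(filtered, scorer, cfg.linking_threshold)
    survivors: list[set[int]] = [set() for _ in video.frames]
    for m in tubelet_members(filtered, pairs):
        if cfg.drop_unmatched and len(m) == 1:
            continue
        mean_cc = np.mean([filtered.frames[t][j].cc for t, j in m], axis=0)
        if float(mean_cc.max()) < cfg.final_score_threshold:
            continue
        for t, j in m:
            survivors[t].add(keep_map[t][j])
    return survivors


class RtReppStream:
    """Streaming post-processor over a sliding buffer of raw frames.

    Frames must be pushed in order starting at frame 0; each push returns the
    refined detections of the newest frame (with absolute frame indices).
    """

    def __init__(
        self,
        frame_width: float,
        frame_height: float,
        fps: float,
        scorer: Optional[LinkScorer] = None,
        cfg: Optional[ReppConfig] = None,
    ) -> None:
        self.scorer = scorer if scorer is not None else LinkScorer.default()
        self.cfg = cfg if cfg is not None else ReppConfig()
        self.frame_width = frame_width
        self.frame_height = frame_height
        self.fps = fps
        self._buffer: deque[list[Detection]] = deque(maxlen=self.cfg.window_size)
        self._next_frame = 0

    @property
    def frame_count(self) -> int:
        """Number of frames pushed so far."""
        return self._next_frame

    def push(self, frame: int, detections: list[Detection]) -> list[Detection]:
        """Push one frame's raw detections; returns that frame's refined output."""
        if frame != self._next_frame:
            raise ValueError(
                f"frames must be pushed in order; expected {self._next_frame}, got {frame}"
            )
        for d in detections:
            if d.frame != frame:
                raise ValueError("detection frame index does not match pushed frame")
        # deque with maxlen evicts the oldest frame automatically when full
        self._buffer.append(list(detections))
        self._next_frame += 1

        start = self._next_frame - len(self._buffer)
        window = VideoPredictions(
            [
                [d.with_frame(d.frame - start) for d in dets]
                for dets in self._buffer
            ],
            self.frame_width,
            self.frame_height,
            self.fps,
        )
        refined = repp(window, self.scorer, self.cfg)
        newest = refined.frames[-1]
        return [d.with_frame(frame) for d in newest]


def rt_repp_replay(
    video: VideoPredictions,
    scorer: Optional[LinkScorer] = None,
    cfg: Optional[ReppConfig] = None,
) -> VideoPredictions:
    """Run the streaming post-processor over a recorded video and collect the
    per-frame outputs into one refined stream (for offline evaluation)."""
    stream = RtReppStream(
        video.frame_width, video.frame_height, video.fps, scorer, cfg
    )
    frames = [stream.push(t, dets) for t, dets in enumerate(video.frames)]
    return VideoPredictions(frames, video.frame_width, video.frame_height, video.fps)
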