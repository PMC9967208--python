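"""Synthetic colonoscopy-like detection streams with known provenance.

The generator emulates the statistical structure the post-processing
relies on, without rendering any images:

* smooth polyp tracks that appear mid-video and move as a clipped random
  walk on box center and size;
* detector box jitter (i.i.d. Gaussian noise on every coordinate) and
  frame-wise misses;
* short-lived spurious false positives (geometric lifetime, mean 1-2
  frames) and rare persistent false positives that sit still for many
  frames — the "static bubble" failure mode that survives temporal
  post-processing because its tubelet is long and confident;
* confidence noise, clipped to [0, 1], with separate levels for true and
  spurious detections;
* appearance embeddings drawn as unit-normalized perturbations of a
  per-object template, so embeddings correlate within a track and decorrelate
  across objects.

All randomness flows through a single ``numpy.random.Generator`` (PCG64,
``numpy.random.default_rng``) seeded once, with draws in a fixed documented
order: per frame, first per-track emission decisions (ascending track id),
then false-positive spawning and emission (spawn order).  Identical
(config, seed) therefore reproduce the stream bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import BoundingBox, Detection, GroundTruthTrack, VideoPredictions
from .errors import ConfigError
from .linking import LinkFeatures, compute_link_features

__all__ = [
    "SimulationConfig",
    "LabeledStream",
    "simulate_tracks",
    "simulate_detections",
    "simulate_stream",
    "labeled_pairs",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic stream; defaults describe a 640x480,
    25 fps, 8 s clip with two polyps and frequent one-frame false positives.

    Rates are per frame; scales are pixels; lifetimes are frames.
    """

    frame_width: float = 640.0
    frame_height: float = 480.0
    fps: float = 25.0
    n_frames: int = 200
    n_tracks: int = 2

    # track geometry and motion
    appear_frame_max_frac: float = 0.3  # tracks appear in the first 30% of frames
    track_min_size: float = 60.0
    track_max_size: float = 120.0
    track_lifetime_mean: float = 150.0
    track_min_lifetime: int = 10
    motion_step: float = 2.0  # random-walk step sd on box center
    size_step: float = 0.5  # random-walk step sd on box width/height

    # detector noise on true tracks
    jitter_scale: float = 2.0  # sd of box-coordinate jitter
    miss_prob: float = 0.1
    tp_conf_mean: float = 0.8
    tp_conf_sd: float = 0.1

    # false positives
    short_fp_rate: float = 0.3  # spawn probability per frame
    short_fp_lifetime_mean: float = 1.5  # geometric mean lifetime
    persistent_fp_rate: float = 0.005
    persistent_fp_lifetime_mean: float = 100.0
    fp_min_size: float = 40.0
    fp_max_size: float = 100.0
    fp_motion_step: float = 1.0
    fp_conf_mean: float = 0.5
    fp_conf_sd: float = 0.15

    # appearance embeddings
    embedding_dim: int = 16
    embedding_noise: float = 0.15  # perturbation scale around the template

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miss_prob", "short_fp_rate", "persistent_fp_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be a probability, got {v}")
        for name in (
            "frame_width",
            "frame_height",
            "fps",
            "track_min_size",
            "track_max_size",
            "fp_min_size",
            "fp_max_size",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.track_max_size >= min(self.frame_width, self.frame_height):
            raise ConfigError("tracks of maximal size cannot fit inside the frame")
        if self.short_fp_lifetime_mean < 1 or self.persistent_fp_lifetime_mean < 1:
            raise ConfigError("geometric lifetime means must be >= 1")
        if self.embedding_dim < 1:
            raise ConfigError("embedding_dim must be >= 1")


@dataclass
class LabeledStream:
    """A simulated detection stream plus its ground truth and per-detection
    provenance.  ``labels[t][i]`` describes ``predictions.frames[t][i]``:
    ``("track", id)``, ``("fp_short", k)`` or ``("fp_persistent", k)``."""

    predictions: VideoPredictions
    truth: list[GroundTruthTrack]
    labels: list[list[tuple[str, int]]]

    def provenance_counts(self) -> dict:
        out: dict = {"track": 0, "fp_short": 0, "fp_persistent": 0}
        for frame in self.labels:
            for kind, _ in frame:
                out[kind] += 1
        return out

    def fp_lifetimes(self) -> dict[tuple[str, int], int]:
        """Emitted lifetime (frame count) of every false-positive instance."""
        life: dict[tuple[str, int], int] = {}
        for frame in self.labels:
            for kind, k in frame:
                if kind != "track":
                    life[(kind, k)] = life.get((kind, k), 0) + 1
        return life


def _clip_center(c: float, half: float, limit: float) -> float:
    return float(np.clip(c, half, limit - half))


def simulate_tracks(
    cfg: SimulationConfig, seed: Optional[int] = None
) -> list[GroundTruthTrack]:
    """Sample ground-truth polyp tracks as clipped random walks."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tracks = []
    appear_max = max(1, int(cfg.n_frames * cfg.appear_frame_max_frac))
    for tid in range(cfg.n_tracks):
        appear = int(rng.integers(0, appear_max))
        lifetime = int(rng.geometric(1.0 / cfg.track_lifetime_mean))
        lifetime = max(cfg.track_min_lifetime, lifetime)
        end = min(cfg.n_frames, appear + lifetime)
        w = float(rng.uniform(cfg.track_min_size, cfg.track_max_size))
        h = float(rng.uniform(cfg.track_min_size, cfg.track_max_size))
        cx = float(rng.uniform(w / 2, cfg.frame_width - w / 2))
        cy = float(rng.uniform(h / 2, cfg.frame_height - h / 2))
        boxes: dict[int, BoundingBox] = {}
        for f in range(appear, end):
            boxes[f] = BoundingBox(x=cx - w / 2, y=cy - h / 2, w=w, h=h)
            # update size first, then clip the center with the new half-extent
            w = float(np.clip(w + rng.normal(0, cfg.size_step), cfg.track_min_size, cfg.track_max_size))
            h = float(np.clip(h + rng.normal(0, cfg.size_step), cfg.track_min_size, cfg.track_max_size))
            cx = _clip_center(cx + rng.normal(0, cfg.motion_step), w / 2, cfg.frame_width)
            cy = _clip_center(cy + rng.normal(0, cfg.motion_step), h / 2, cfg.frame_height)
        tracks.append(GroundTruthTrack(track_id=tid, boxes=boxes))
    return tracks


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


class _FalsePositive:
    __slots__ = ("kind", "key", "cx", "cy", "w", "h", "remaining", "template")

    def __init__(self, kind, key, cx, cy, w, h, remaining, template):
        self.kind = kind
        self.key = key
        self.cx, self.cy, self.w, self.h = cx, cy, w, h
        self.remaining = remaining
        self.template = template


def simulate_detections(
    tracks: Sequence[GroundTruthTrack],
    cfg: SimulationConfig,
    seed: Optional[int] = None,
) -> LabeledStream:
    """Emit a noisy detector stream for the given tracks, with provenance."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    templates = {
        t.track_id: _unit(rng.standard_normal(cfg.embedding_dim)) for t in tracks
    }
    frames: list[list[Detection]] = []
    labels: list[list[tuple[str, int]]] = []
    active_fps: list[_FalsePositive] = []
    n_short = n_persistent = 0

    for f in range(cfg.n_frames):
        dets: list[Detection] = []
        labs: list[tuple[str, int]] = []
        # true-track emissions, ascending track id
        for t in tracks:
            if f not in t.boxes:
                continue
            missed = rng.random() < cfg.miss_prob
            box = t.boxes[f]
            noise = rng.normal(0, cfg.jitter_scale, size=4)
            conf = float(np.clip(rng.normal(cfg.tp_conf_mean, cfg.tp_conf_sd), 0, 1))
            emb = _unit(
                templates[t.track_id]
                + cfg.embedding_noise * rng.standard_normal(cfg.embedding_dim)
            )
            if missed:
                continue
            jittered = BoundingBox(
                x=box.x + noise[0],
                y=box.y + noise[1],
                w=max(1.0, box.w + noise[2]),
                h=max(1.0, box.h + noise[3]),
            )
            dets.append(
                Detection(frame=f, box=jittered, cc=np.array([conf]), app=emb)
            )
            labs.append(("track", int(t.track_id)))

        # spawn new false positives
        if rng.random() < cfg.short_fp_rate:
            w = float(rng.uniform(cfg.fp_min_size, cfg.fp_max_size))
            h = float(rng.uniform(cfg.fp_min_size, cfg.fp_max_size))
            active_fps.append(
                _FalsePositive(
                    "fp_short",
                    n_short,
                    float(rng.uniform(w / 2, cfg.frame_width - w / 2)),
                    float(rng.uniform(h / 2, cfg.frame_height - h / 2)),
                    w,
                    h,
                    int(rng.geometric(1.0 / cfg.short_fp_lifetime_mean)),
                    _unit(rng.standard_normal(cfg.embedding_dim)),
                )
            )
            n_short += 1
        if rng.random() < cfg.persistent_fp_rate:
            w = float(rng.uniform(cfg.fp_min_size, cfg.fp_max_size))
            h = float(rng.uniform(cfg.fp_min_size, cfg.fp_max_size))
            active_fps.append(
                _FalsePositive(
                    "fp_persistent",
                    n_persistent,
                    float(rng.uniform(w / 2, cfg.frame_width - w / 2)),
                    float(rng.uniform(h / 2, cfg.frame_height - h / 2)),
                    w,
                    h,
                    int(rng.geometric(1.0 / cfg.persistent_fp_lifetime_mean)),
                    _unit(rng.standard_normal(cfg.embedding_dim)),
                )
            )
            n_persistent += 1

        # emit active false positives, spawn order
        survivors: list[_FalsePositive] = []
        for fp in active_fps:
            conf = float(np.clip(rng.normal(cfg.fp_conf_mean, cfg.fp_conf_sd), 0, 1))
            emb = _unit(
                fp.template + cfg.embedding_noise * rng.standard_normal(cfg.embedding_dim)
            )
            dets.append(
                Detection(
                    frame=f,
                    box=BoundingBox(
                        x=fp.cx - fp.w / 2, y=fp.cy - fp.h / 2, w=fp.w, h=fp.h
                    ),
                    cc=np.array([conf]),
                    app=emb,
                )
            )
            labs.append((fp.kind, fp.key))
            fp.remaining -= 1
            if fp.remaining > 0:
                fp.cx = _clip_center(
                    fp.cx + rng.normal(0, cfg.fp_motion_step), fp.w / 2, cfg.frame_width
                )
                fp.cy = _clip_center(
                    fp.cy + rng.normal(0, cfg.fp_motion_step), fp.h / 2, cfg.frame_height
                )
                survivors.append(fp)
        active_fps = survivors
        frames.append(dets)
        labels.append(labs)

    predictions = VideoPredictions(
        frames, cfg.frame_width, cfg.frame_height, cfg.fps
    )
    return LabeledStream(predictions=predictions, truth=list(tracks), labels=labels)


def simulate_stream(cfg: SimulationConfig, seed: Optional[int] = None) -> LabeledStream:
    """Convenience wrapper: tracks and detections from one seed.

    Track and detector randomness use two child seeds spawned from the given
    seed so the two stages stay independently reproducible.
    """
    base = cfg.seed if seed is None else seed
    ss_tracks, ss_dets = np.random.SeedSequence(base).spawn(2)
    tracks = simulate_tracks(cfg, seed=ss_tracks.generate_state(1)[0] % (2**31))
    return simulate_detections(tracks, cfg, seed=ss_dets.generate_state(1)[0] % (2**31))


def labeled_pairs(
    stream: LabeledStream,
    cfg: SimulationConfig,
    seed: Optional[int] = None,
    max_pairs: Optional[int] = None,
) -> list[tuple[LinkFeatures, bool]]:
    """Training examples for the link scorer, labeled from provenance.

    Same-instance pairs are every consecutive-frame detection pair with
    identical provenance; different-instance pairs are sampled from the
    cross pairs, subsampled to match the same-pair count so classes stay
    balanced.  Raises when the stream contains no same-instance pair.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    video = stream.predictions
    same: list[LinkFeatures] = []
    diff: list[LinkFeatures] = []
    for t in range(video.n_frames - 1):
        for i, d1 in enumerate(video.frames[t]):
            for j, d2 in enumerate(video.frames[t + 1]):
                f = compute_link_features(
                    d1, d2, video.frame_width, video.frame_height
                )
                if stream.labels[t][i] == stream.labels[t + 1][j]:
                    same.append(f)
                else:
                    diff.append(f)
    if not same:
        raise ValueError("stream contains no same-instance consecutive pairs")
    if len(diff) > len(same):
        idx = rng.choice(len(diff), size=len(same), replace=False)
        diff = [diff[i] for i in sorted(idx)]
    pairs = [(f, True) for f in same] + [(f, False) for f in diff]
    if max_pairs is not None and len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    return pairs
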