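"""Domain types and bounding-box geometry shared by every pipeline stage.

Boxes use the detector convention: ``(x, y)`` is the upper-left corner in
pixels (origin at the image's upper-left, y growing downward), ``w``/``h``
are width and height.  Coordinates are continuous; the box area is ``w * h``
with no pixel-grid half-open correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidBoxError

__all__ = [
    "BoundingBox",
    "Detection",
    "VideoPredictions",
    "Tubelet",
    "GroundTruthTrack",
    "iou",
    "center_distance",
    "size_ratios",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, upper-left corner + extent, in pixels."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidBoxError(f"non-finite box coordinate {name}={v!r}")
        if self.w <= 0 or self.h <= 0:
            raise InvalidBoxError(
                f"box extents must be positive, got w={self.w}, h={self.h}"
            )

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_xywh(self) -> list[float]:
        return [self.x, self.y, self.w, self.h]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when identical."""
    ix = min(a.x + a.w, b.x + b.w) - max(a.x, b.x)
    iy = min(a.y + a.h, b.y + b.h) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    # clamp: a.area + b.area - inter can round just below inter
    return min(1.0, inter / (a.area + b.area - inter))


def center_distance(
    a: BoundingBox, b: BoundingBox, frame_width: float, frame_height: float
) -> float:
    """Euclidean distance between box centers, normalized by the frame diagonal.

    Normalizing by the diagonal makes the feature resolution-independent and
    bounds it by 1 whenever both centers lie inside the frame.
    """
    if frame_width <= 0 or frame_height <= 0:
        raise InvalidBoxError(
            f"frame dimensions must be positive, got {frame_width}x{frame_height}"
        )
    (ax, ay), (bx, by) = a.center, b.center
    diag = math.hypot(frame_width, frame_height)
    return math.hypot(ax - bx, ay - by) / diag


def size_ratios(a: BoundingBox, b: BoundingBox) -> tuple[float, float]:
    """Width and height similarity ratios, each ``min/max`` so the pair is
    symmetric in its arguments and confined to ``(0, 1]``; 1 means equal size."""
    rw = min(a.w, b.w) / max(a.w, b.w)
    rh = min(a.h, b.h) / max(a.h, b.h)
    return (rw, rh)


_APP_NORM_TOL = 1e-6


@dataclass(eq=False)
class Detection:
    """One detected object in one frame.

    Parameters
    ----------
    frame
        0-based frame index within the video.
    box
        Bounding box in pixel coordinates.
    cc
        Class-confidence vector, each entry in [0, 1].  Single class
        (polyp detection) means length 1, but any C >= 1 is supported.
    objectness
        Optional detector objectness in [0, 1]; defaults to 1 and is carried
        through unchanged by the post-processing.
    app
        Optional L2-normalized appearance embedding of the image patch.
    """

    frame: int
    box: BoundingBox
    cc: np.ndarray
    objectness: float = 1.0
    app: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cc = np.asarray(self.cc, dtype=float)
        if self.cc.ndim != 1 or self.cc.size < 1:
            raise ValueError("cc must be a 1-D vector of length >= 1")
        if np.any(self.cc < 0) or np.any(self.cc > 1):
            raise ValueError("class confidences must lie in [0, 1]")
        if not 0 <= self.objectness <= 1:
            raise ValueError("objectness must lie in [0, 1]")
        if self.app is not None:
            self.app = np.asarray(self.app, dtype=float)
            norm = float(np.linalg.norm(self.app))
            if abs(norm - 1.0) > _APP_NORM_TOL:
                raise ValueError(
                    f"appearance embedding must be unit-norm, got ||app|| = {norm}"
                )

    @property
    def score(self) -> float:
        """Scalar confidence: the maximum class confidence."""
        return float(self.cc.max())

    def with_frame(self, frame: int) -> "Detection":
        return replace(self, frame=frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Detection):
            return NotImplemented
        return (
            self.frame == other.frame
            and self.box == other.box
            and np.array_equal(self.cc, other.cc)
            and self.objectness == other.objectness
            and (
                (self.app is None and other.app is None)
                or (
                    self.app is not None
                    and other.app is not None
                    and np.array_equal(self.app, other.app)
                )
            )
        )


@dataclass
class VideoPredictions:
    """Ordered per-frame detection lists for one video."""

    frames: list[list[Detection]]
    frame_width: float
    frame_height: float
    fps: float

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a video must contain at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for t, dets in enumerate(self.frames):
            for d in dets:
                if d.frame != t:
                    raise ValueError(
                        f"detection frame index {d.frame} does not match position {t}"
                    )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_detections(self) -> int:
        return sum(len(f) for f in self.frames)

    def window(self, start: int, stop: int) -> "VideoPredictions":
        """Sub-video over frames [start, stop), re-indexed to start at 0."""
        if not (0 <= start < stop <= self.n_frames):
            raise ValueError(f"invalid window [{start}, {stop})")
        frames = [
            [d.with_frame(d.frame - start) for d in self.frames[t]]
            for t in range(start, stop)
        ]
        return VideoPredictions(frames, self.frame_width, self.frame_height, self.fps)

    def all_detections(self) -> Iterator[Detection]:
        for dets in self.frames:
            yield from dets


@dataclass
class Tubelet:
    """A maximal run of detections in strictly consecutive frames that the
    linker attributes to one object instance."""

    start_frame: int
    detections: list[Detection]
    id: int = 0

    def __post_init__(self) -> None:
        if not self.detections:
            raise ValueError("a tubelet must contain at least one detection")
        for k, d in enumerate(self.detections):
            if d.frame != self.start_frame + k:
                raise ValueError(
                    "tubelet detections must occupy strictly consecutive frames"
                )

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def end_frame(self) -> int:
        """Last frame index covered (inclusive)."""
        return self.start_frame + len(self.detections) - 1


@dataclass
class GroundTruthTrack:
    """One annotated object: per-frame boxes for every frame it is visible."""

    track_id: object
    boxes: dict[int, BoundingBox] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.boxes:
            raise ValueError("a ground-truth track must contain at least one box")

    @property
    def first_frame(self) -> int:
        """The frame in which the object first becomes visible."""
        return min(self.boxes)
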