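"""Detection linking: similarity features, link scores, per-frame-pair
assignment and tubelet assembly.

Two detections in consecutive frames are compared through four feature
groups: location (IoU and relative center distance), geometry (width/height
ratios), appearance (Euclidean distance between patch embeddings, when the
detector provides them) and semantics (dot product of the class-confidence
vectors).  The link score multiplies the semantic similarity with a logistic
regression over the remaining features,

    LS(o_t, o_{t+1}) = fsem * sigmoid(w . [floc, fgeo, fapp] + b)

so a pair whose class confidences vanish can never link regardless of how
well the boxes align.  Per frame transition, a maximum-total-score one-to-one
assignment (Hungarian) pairs detections whose score reaches the linking
threshold; chains of pairs become tubelets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.linear_model import LogisticRegression

from .core import Detection, Tubelet, VideoPredictions, center_distance, iou, size_ratios
from .errors import ConfigError, DegenerateTrainingError

__all__ = [
    "LinkFeatures",
    "LinkScorer",
    "DEFAULT_LINK_THRESHOLD",
    "compute_link_features",
    "link_score",
    "fit_link_scorer",
    "solve_assignment",
    "get_pairs",
    "tubelet_members",
    "build_tubelets",
]

#: Linking-score threshold found most effective for polyp streams.
DEFAULT_LINK_THRESHOLD = 0.2

FEATURE_NAMES = ("iou", "dcenters", "ratio_w", "ratio_h", "dapp")


@dataclass(frozen=True)
class LinkFeatures:
    """Pairwise similarity features between two consecutive-frame detections."""

    iou: float
    dcenters: float
    ratio_w: float
    ratio_h: float
    fsem: float
    dapp: Optional[float] = None

    def get(self, name: str) -> float:
        v = getattr(self, name)
        if v is None:
            raise ConfigError(
                f"feature {name!r} requested but absent (no appearance embeddings?)"
            )
        return float(v)


def compute_link_features(
    d1: Detection, d2: Detection, frame_width: float, frame_height: float
) -> LinkFeatures:
    """Features for a candidate link between detections in frames t and t+1.

    ``dapp`` is populated only when both detections carry an appearance
    embedding; ``fsem`` is the dot product of the class-confidence vectors.
    """
    if d2.frame != d1.frame + 1:
        raise ValueError(
            f"detections must be in consecutive frames, got {d1.frame} and {d2.frame}"
        )
    dapp = None
    if d1.app is not None and d2.app is not None:
        dapp = float(np.linalg.norm(d1.app - d2.app))
    rw, rh = size_ratios(d1.box, d2.box)
    return LinkFeatures(
        iou=iou(d1.box, d2.box),
        dcenters=center_distance(d1.box, d2.box, frame_width, frame_height),
        ratio_w=rw,
        ratio_h=rh,
        fsem=float(np.dot(d1.cc, d2.cc)),
        dapp=dapp,
    )


# Default weights for the logistic combination, used when no trained scorer is
# supplied.  Chosen so that near-identical boxes (IoU ~ 0.9, tiny center
# offset) score close to 1 while boxes that overlap less than about half, or
# sit far apart, fall below the 0.2 linking threshold even at full semantic
# similarity.
_DEFAULT_COEFFICIENTS = {
    "iou": 12.0,
    "dcenters": -10.0,
    "ratio_w": 2.0,
    "ratio_h": 2.0,
}
_DEFAULT_INTERCEPT = -9.0


@dataclass
class LinkScorer:
    """Logistic link-score model: per-feature weights plus intercept.

    The feature set in use is exactly the keys of ``coefficients``; ``dapp``
    is included only for detectors that emit appearance embeddings.
    """

    coefficients: dict[str, float]
    intercept: float

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(FEATURE_NAMES)
        if unknown:
            raise ConfigError(f"unknown link features: {sorted(unknown)}")
        if not self.coefficients:
            raise ConfigError("a link scorer needs at least one feature")

    @property
    def feature_set(self) -> tuple[str, ...]:
        return tuple(n for n in FEATURE_NAMES if n in self.coefficients)

    @classmethod
    def default(cls) -> "LinkScorer":
        return cls(dict(_DEFAULT_COEFFICIENTS), _DEFAULT_INTERCEPT)

    def logit(self, f: LinkFeatures) -> float:
        return self.intercept + sum(
            w * f.get(name) for name, w in self.coefficients.items()
        )

    def score(self, f: LinkFeatures) -> float:
        """Link score in [0, 1]: fsem times the logistic of the linear term."""
        if f.fsem == 0.0:
            return 0.0
        z = self.logit(f)
        # numerically safe sigmoid
        if z >= 0:
            s = 1.0 / (1.0 + math.exp(-z))
        else:
            e = math.exp(z)
            s = e / (1.0 + e)
        return f.fsem * s

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "features": list(self.feature_set),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinkScorer":
        try:
            return cls(dict(d["coefficients"]), float(d["intercept"]))
        except KeyError as e:
            raise ConfigError(f"scorer file missing key {e}") from e

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "LinkScorer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def link_score(f: LinkFeatures, scorer: LinkScorer) -> float:
    """Evaluate the multiplicative link score for one feature vector."""
    return scorer.score(f)


def fit_link_scorer(
    pairs: Sequence[tuple[LinkFeatures, bool]],
    features: Sequence[str] = ("iou", "dcenters", "ratio_w", "ratio_h"),
    C: float = 1.0,
    seed: int = 0,
) -> LinkScorer:
    """Train the logistic regression X to separate same-instance from
    different-instance detection pairs.

    Parameters
    ----------
    pairs
        (features, label) examples; label True means the two detections
        belong to the same object instance.
    features
        Which features enter the linear term; ``fsem`` never does, it stays
        the outer multiplier of the link score.

    The fit is deterministic: lbfgs with a fixed seed and iteration cap.
    """
    for name in features:
        if name not in FEATURE_NAMES:
            raise ConfigError(f"unknown feature {name!r}")
        if name == "fsem":
            raise ConfigError("fsem is the multiplicative factor, not a regressor input")
    labels = np.array([bool(y) for _, y in pairs])
    if labels.size < 4 or labels.sum() < 2 or (~labels).sum() < 2:
        raise DegenerateTrainingError(
            "need at least two examples of each label to fit the link scorer"
        )
    X = np.array([[f.get(name) for name in features] for f, _ in pairs])
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=1000, random_state=seed)
    clf.fit(X, labels.astype(int))
    coef = {name: float(w) for name, w in zip(features, clf.coef_[0])}
    return LinkScorer(coef, float(clf.intercept_[0]))


def solve_assignment(
    scores: np.ndarray, min_score: float = DEFAULT_LINK_THRESHOLD
) -> list[tuple[int, int]]:
    """Maximum-total-score one-to-one matching between two detection sets.

    Entries below ``min_score`` are infeasible: leaving a detection unmatched
    is always preferred over pairing it below threshold.  Solved with the
    Hungarian algorithm on a matrix where infeasible entries contribute
    nothing, which is equivalent to optimizing over feasible partial
    matchings only.  Returns index pairs sorted lexicographically.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return []
    if not np.all(np.isfinite(scores)):
        raise ValueError("link scores must be finite")
    feasible = scores >= min_score
    padded = np.where(feasible, scores, 0.0)
    rows, cols = linear_sum_assignment(padded, maximize=True)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]
    pairs.sort()
    return pairs


def get_pairs(
    video: VideoPredictions,
    scorer: LinkScorer,
    min_score: float = DEFAULT_LINK_THRESHOLD,
) -> list[list[tuple[int, int]]]:
    """Linked index pairs for every frame transition t -> t+1.

    Transitions where either frame has no detections yield an empty pair
    list.  Element t of the result refers to detections ``frames[t][i]`` and
    ``frames[t+1][j]``.
    """
    out: list[list[tuple[int, int]]] = []
    for t in range(video.n_frames - 1):
        a, b = video.frames[t], video.frames[t + 1]
        if not a or not b:
            out.append([])
            continue
        m = np.empty((len(a), len(b)))
        for i, d1 in enumerate(a):
            for j, d2 in enumerate(b):
                f = compute_link_features(
                    d1, d2, video.frame_width, video.frame_height
                )
                m[i, j] = scorer.score(f)
        out.append(solve_assignment(m, min_score))
    return out


def tubelet_members(
    video: VideoPredictions, pairs: list[list[tuple[int, int]]]
) -> list[list[tuple[int, int]]]:
    """Tubelet membership as (frame, detection-index) positions.

    A detection without an incoming pair starts a new tubelet; a paired
    detection extends its predecessor's tubelet.  Every detection lands in
    exactly one tubelet and tubelets span strictly consecutive frames.
    """
    if len(pairs) != max(video.n_frames - 1, 0):
        raise ValueError(
            f"expected {video.n_frames - 1} pair lists, got {len(pairs)}"
        )
    members: list[list[tuple[int, int]]] = []
    # tubelet index currently ending at each detection of the previous frame
    prev_owner: dict[int, int] = {}
    for t, dets in enumerate(video.frames):
        incoming: dict[int, int] = {}
        if t > 0:
            seen_i: set[int] = set()
            seen_j: set[int] = set()
            for i, j in pairs[t - 1]:
                if not (0 <= i < len(video.frames[t - 1]) and 0 <= j < len(dets)):
                    raise ValueError(f"pair ({i}, {j}) out of range at transition {t - 1}")
                if i in seen_i or j in seen_j:
                    raise ValueError(f"pair list at transition {t - 1} is not one-to-one")
                seen_i.add(i)
                seen_j.add(j)
                incoming[j] = prev_owner[i]
        owner: dict[int, int] = {}
        for j in range(len(dets)):
            if j in incoming:
                idx = incoming[j]
                members[idx].append((t, j))
            else:
                idx = len(members)
                members.append([(t, j)])
            owner[j] = idx
        prev_owner = owner
    return members


def build_tubelets(
    video: VideoPredictions, pairs: list[list[tuple[int, int]]]
) -> list[Tubelet]:
    """Assemble :class:`Tubelet` objects from per-transition linked pairs."""
    return [
        Tubelet(
            start_frame=m[0][0],
            detections=[video.frames[t][j] for t, j in m],
            id=k,
        )
        for k, m in enumerate(tubelet_members(video, pairs))
    ]
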