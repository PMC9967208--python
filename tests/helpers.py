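"""Shared test helpers and independent oracles.

The oracles here are deliberately naive re-implementations (enumeration,
direct convolution, staircase integration) kept independent of the package
internals they check.
"""

from __future__ import annotations

import numpy as np

from rtrepp import BoundingBox, Detection, VideoPredictions


def det(frame, x, y, w, h, conf=0.9, app=None, cc=None) -> Detection:
    return Detection(
        frame=frame,
        box=BoundingBox(x, y, w, h),
        cc=np.array([conf]) if cc is None else np.asarray(cc, float),
        app=app,
    )


def video_from(frames, width=640.0, height=480.0, fps=25.0) -> VideoPredictions:
    return VideoPredictions(list(frames), width, height, fps)


def brute_force_matchings(scores, min_score):
    """Enumerate every one-to-one partial matching over feasible entries.

    Returns (best_total, list of optimal matchings as frozensets of (i, j)).
    """
    scores = np.asarray(scores, float)
    n1, n2 = scores.shape
    best_total = -1.0
    best: list[frozenset] = []

    def recurse(i, used_cols, total, chosen):
        nonlocal best_total, best
        if i == n1:
            if total > best_total + 1e-12:
                best_total, best = total, [frozenset(chosen)]
            elif abs(total - best_total) <= 1e-12:
                best.append(frozenset(chosen))
            return
        recurse(i + 1, used_cols, total, chosen)  # leave row i unmatched
        for j in range(n2):
            if j not in used_cols and scores[i, j] >= min_score:
                recurse(i + 1, used_cols | {j}, total + scores[i, j], chosen + [(i, j)])

    recurse(0, frozenset(), 0.0, [])
    return best_total, best


def gaussian_smooth_oracle(series, sigma):
    """Direct discrete Gaussian convolution, half-sample-reflect boundary,
    kernel truncated at 4 sigma — coded independently of scipy.ndimage."""
    series = np.asarray(series, float)
    radius = int(4.0 * sigma + 0.5)
    if radius == 0:
        return series.copy()
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    n = len(series)
    # half-sample symmetric padding (d c b a | a b c d | d c b a), which is
    # periodic with period 2n in the doubled sequence
    reflected = np.concatenate([series, series[::-1]])
    padded = np.empty(n + 2 * radius)
    for k in range(len(padded)):
        # map position k-radius into the period-2n reflected sequence
        p = (k - radius) % (2 * n)
        padded[k] = reflected[p]
    out = np.empty(n)
    for i in range(n):
        out[i] = float(np.dot(padded[i : i + 2 * radius + 1], kernel[::-1]))
    return out


def ap_oracle(streams, iou_threshold=0.5):
    """Brute-force PR-staircase integration of average precision.

    Does its own ranking and greedy per-frame matching in plain loops, then
    uses the max-precision-to-the-right identity for all-point AP.
    """

    def overlap(a, b):
        ix = min(a.x + a.w, b.x + b.w) - max(a.x, b.x)
        iy = min(a.y + a.h, b.y + b.h) - max(a.y, b.y)
        if ix <= 0 or iy <= 0:
            return 0.0
        inter = ix * iy
        return inter / (a.w * a.h + b.w * b.h - inter)

    pool = []
    n_gt = 0
    for v, (video, tracks) in enumerate(streams):
        for track in tracks:
            n_gt += len(track.boxes)
        for t, dets in enumerate(video.frames):
            for i, d in enumerate(dets):
                pool.append((-d.score, v, t, i))
    pool.sort()
    claimed = set()
    flags = []
    for _, v, t, i in pool:
        video, tracks = streams[v]
        d = video.frames[t][i]
        best, best_ov = None, 0.0
        for track in tracks:
            if t in track.boxes and (v, t, track.track_id) not in claimed:
                ov = overlap(d.box, track.boxes[t])
                if ov > best_ov:
                    best, best_ov = track.track_id, ov
        if best is not None and best_ov >= iou_threshold:
            claimed.add((v, t, best))
            flags.append(True)
        else:
            flags.append(False)
    precisions = []
    tp = 0
    for k, f in enumerate(flags):
        tp += f
        precisions.append(tp / (k + 1))
    ap = 0.0
    for k, f in enumerate(flags):
        if f:
            ap += max(precisions[k:])
    return ap / n_gt
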