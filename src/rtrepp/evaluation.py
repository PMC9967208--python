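"""Benchmark protocol for video polyp detection.

Matching: a detection counts as a true positive when its box overlaps a
ground-truth box by at least 50% (IoU by default).  Matching within a frame
is greedy by confidence, one-to-one.  Dataset metrics are micro means —
TP/FP/FN counts pooled over every image before precision/recall/F1 are
computed once.  Average precision integrates the precision–recall curve
obtained by ranking all detections by confidence.  First detection time
(FDT) is the latency, in seconds, between a polyp becoming visible and its
first matched detection.  False-positive statistics are reported per video.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .core import BoundingBox, Detection, GroundTruthTrack, VideoPredictions, iou

__all__ = [
    "FrameMatchResult",
    "match_frame",
    "match_video",
    "precision_recall_f1",
    "average_precision",
    "first_detection_time",
    "false_positive_stats",
    "micro_mean",
    "evaluate_video",
    "evaluate_dataset",
    "report_table",
]

OverlapMode = Literal["iou", "gt_coverage"]


def _overlap(det_box: BoundingBox, gt_box: BoundingBox, mode: OverlapMode) -> float:
    if mode == "iou":
        return iou(det_box, gt_box)
    # alternative reading of "overlap at least 50%": intersection covering
    # at least half the annotated box
    ix = min(det_box.x + det_box.w, gt_box.x + gt_box.w) - max(det_box.x, gt_box.x)
    iy = min(det_box.y + det_box.h, gt_box.y + gt_box.h) - max(det_box.y, gt_box.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    return (ix * iy) / gt_box.area


@dataclass
class FrameMatchResult:
    """Outcome of matching one frame's detections against its annotations."""

    tp: list[tuple[int, object]] = field(default_factory=list)  # (det index, track id)
    fp: list[int] = field(default_factory=list)  # unmatched detection indices
    fn: list[object] = field(default_factory=list)  # unmatched track ids

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def n_fp(self) -> int:
        return len(self.fp)

    @property
    def n_fn(self) -> int:
        return len(self.fn)


def match_frame(
    detections: Sequence[Detection],
    gt_boxes: dict,
    iou_threshold: float = 0.5,
    mode: OverlapMode = "iou",
) -> FrameMatchResult:
    """Greedy one-to-one matching of one frame.

    Detections, in descending confidence order, each claim the still
    unclaimed ground-truth box of highest overlap, provided the overlap
    reaches the threshold.  Remaining detections are false positives,
    unclaimed annotations false negatives.
    """
    result = FrameMatchResult()
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].score, i))
    gt_ids = list(gt_boxes.keys())
    claimed: set = set()
    for i in order:
        best_id, best_ov = None, 0.0
        for tid in gt_ids:
            if tid in claimed:
                continue
            ov = _overlap(detections[i].box, gt_boxes[tid], mode)
            if ov > best_ov:
                best_id, best_ov = tid, ov
        if best_id is not None and best_ov >= iou_threshold:
            claimed.add(best_id)
            result.tp.append((i, best_id))
        else:
            result.fp.append(i)
    result.fn = [tid for tid in gt_ids if tid not in claimed]
    return result


def _gt_boxes_at(tracks: Iterable[GroundTruthTrack], frame: int) -> dict:
    return {t.track_id: t.boxes[frame] for t in tracks if frame in t.boxes}


def match_video(
    video: VideoPredictions,
    tracks: Sequence[GroundTruthTrack],
    iou_threshold: float = 0.5,
    mode: OverlapMode = "iou",
) -> list[FrameMatchResult]:
    """Per-frame match results for one video."""
    return [
        match_frame(video.frames[t], _gt_boxes_at(tracks, t), iou_threshold, mode)
        for t in range(video.n_frames)
    ]


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 as percentages.

    Zero-denominator convention: a metric whose denominator is zero is
    reported as 0 (so an empty video scores 0 across the board).
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 200.0 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
    return (precision, recall, f1)


def average_precision(
    streams: Sequence[tuple[VideoPredictions, Sequence[GroundTruthTrack]]],
    iou_threshold: float = 0.5,
    mode: OverlapMode = "iou",
    interpolation: Literal["all", "11point"] = "all",
) -> float:
    """Area under the precision–recall curve, detections pooled over videos.

    All detections are ranked by confidence (descending, stable within
    ties).  Walking down the ranking, each detection greedily claims the
    best unclaimed ground-truth box of its frame; precision and recall at
    every rank trace the PR curve.  ``all`` integrates the monotonized
    all-point curve; ``11point`` averages interpolated precision at recalls
    0, 0.1, ..., 1.
    """
    n_gt = sum(
        len(t.boxes) for _, tracks in streams for t in tracks
    )
    if n_gt == 0:
        raise ValueError("average precision is undefined without ground truth")

    ranked: list[tuple[float, int, int, int]] = []  # (-score, video, frame, det idx)
    for v, (video, _) in enumerate(streams):
        for t, dets in enumerate(video.frames):
            for i, d in enumerate(dets):
                ranked.append((-d.score, v, t, i))
    ranked.sort()

    claimed: set[tuple[int, int, object]] = set()
    tp_flags = np.zeros(len(ranked), dtype=bool)
    for k, (_, v, t, i) in enumerate(ranked):
        video, tracks = streams[v]
        det = video.frames[t][i]
        gt_boxes = _gt_boxes_at(tracks, t)
        best_id, best_ov = None, 0.0
        for tid, box in gt_boxes.items():
            if (v, t, tid) in claimed:
                continue
            ov = _overlap(det.box, box, mode)
            if ov > best_ov:
                best_id, best_ov = tid, ov
        if best_id is not None and best_ov >= iou_threshold:
            claimed.add((v, t, best_id))
            tp_flags[k] = True

    if len(ranked) == 0:
        return 0.0
    cum_tp = np.cumsum(tp_flags)
    precision = cum_tp / np.arange(1, len(ranked) + 1)
    recall = cum_tp / n_gt

    if interpolation == "11point":
        ap = 0.0
        for r in np.linspace(0, 1, 11):
            mask = recall >= r
            ap += precision[mask].max() if mask.any() else 0.0
        return float(ap / 11.0)

    # all-point: monotonize precision from the right, integrate over recall
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    return float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))


#: Sentinel: the track was never matched by any detection.
NEVER_DETECTED = None


def first_detection_time(
    video: VideoPredictions,
    track: GroundTruthTrack,
    iou_threshold: float = 0.5,
    mode: OverlapMode = "iou",
) -> Optional[float]:
    """Seconds from a track's first visible frame to its first matched
    detection; ``None`` when the track is never detected."""
    if video.fps <= 0:
        raise ValueError("fps must be positive")
    for f in sorted(track.boxes):
        gt_box = track.boxes[f]
        if f >= video.n_frames:
            break
        for d in video.frames[f]:
            if _overlap(d.box, gt_box, mode) >= iou_threshold:
                return (f - track.first_frame) / video.fps
    return NEVER_DETECTED


def false_positive_stats(
    match_results: Sequence[FrameMatchResult],
    tracks: Sequence[GroundTruthTrack],
    fpr_mode: Literal["negative_frames", "all_frames"] = "negative_frames",
) -> tuple[int, Optional[float]]:
    """Per-video false-positive count and false-positive rate (percent).

    ``negative_frames`` (default): fraction of annotation-free frames that
    contain at least one detection.  ``all_frames``: fraction of all frames
    containing at least one false-positive detection.  With no negative
    frames the default rate is undefined and reported as ``None``.
    """
    fp_count = sum(r.n_fp for r in match_results)
    positive_frames = {f for t in tracks for f in t.boxes}
    if fpr_mode == "all_frames":
        frames_with_fp = sum(1 for r in match_results if r.n_fp > 0)
        return fp_count, 100.0 * frames_with_fp / len(match_results)
    negative = [
        r for f, r in enumerate(match_results) if f not in positive_frames
    ]
    if not negative:
        return fp_count, None
    hit = sum(1 for r in negative if r.n_tp + r.n_fp > 0)
    return fp_count, 100.0 * hit / len(negative)


def micro_mean(per_video_counts: Iterable[tuple[int, int, int]]) -> dict:
    """Dataset metrics from counts pooled over every image of every video."""
    tp = fp = fn = 0
    for a, b, c in per_video_counts:
        tp, fp, fn = tp + a, fp + b, fn + c
    p, r, f1 = precision_recall_f1(tp, fp, fn)
    return {"tp": tp, "fp": fp, "fn": fn, "precision": p, "recall": r, "f1": f1}


def evaluate_video(
    video: VideoPredictions,
    tracks: Sequence[GroundTruthTrack],
    iou_threshold: float = 0.5,
    mode: OverlapMode = "iou",
    fdt_aggregate: Literal["mean", "max"] = "mean",
    fpr_mode: Literal["negative_frames", "all_frames"] = "negative_frames",
) -> dict:
    """Full single-video report: counts, P/R/F1, AP, FDT, FP and FPR."""
    results = match_video(video, tracks, iou_threshold, mode)
    tp = sum(r.n_tp for r in results)
    fp = sum(r.n_fp for r in results)
    fn = sum(r.n_fn for r in results)
    p, r, f1 = precision_recall_f1(tp, fp, fn)
    ap = (
        average_precision([(video, tracks)], iou_threshold, mode)
        if any(t.boxes for t in tracks)
        else None
    )
    fdts = {
        t.track_id: first_detection_time(video, t, iou_threshold, mode)
        for t in tracks
    }
    detected = [v for v in fdts.values() if v is not None]
    if detected:
        fdt = max(detected) if fdt_aggregate == "max" else float(np.mean(detected))
    else:
        fdt = None
    fp_count, fpr = false_positive_stats(results, tracks, fpr_mode)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": round(p, 2),
        "recall": round(r, 2),
        "f1": round(f1, 2),
        "map": round(100.0 * ap, 2) if ap is not None else None,
        "fdt": {str(k): v for k, v in fdts.items()},
        "fdt_aggregate": fdt,
        "fp_count": fp_count,
        "fpr": round(fpr, 2) if fpr is not None else None,
    }


def evaluate_dataset(
    streams: Sequence[tuple[VideoPredictions, Sequence[GroundTruthTrack]]],
    iou_threshold: float = 0.5,
    mode: OverlapMode = "iou",
    **kwargs,
) -> dict:
    """Per-video reports plus the pooled micro-mean row and dataset mAP.

    mAP is reported both ways the pooling can be read: detections pooled
    across videos before the PR curve is built (``map_pooled``) and the
    unweighted mean of per-video APs (``map_per_video_mean``).
    """
    videos = [
        evaluate_video(v, g, iou_threshold, mode, **kwargs) for v, g in streams
    ]
    pooled = micro_mean((r["tp"], r["fp"], r["fn"]) for r in videos)
    pooled = {k: round(v, 2) if isinstance(v, float) else v for k, v in pooled.items()}
    aps = [r["map"] for r in videos if r["map"] is not None]
    return {
        "videos": videos,
        "micro_mean": pooled,
        "map_pooled": round(100.0 * average_precision(streams, iou_threshold, mode), 2),
        "map_per_video_mean": round(float(np.mean(aps)), 2) if aps else None,
    }


def report_table(report: dict) -> str:
    """Aligned plain-text table: one row per video plus the micro-mean row."""
    header = ["video", "mAP", "F1", "FDT", "FP", "FPR"]
    rows = [header]
    for i, r in enumerate(report["videos"], start=1):
        rows.append(
            [
                str(i),
                "-" if r["map"] is None else f"{r['map']:.2f}",
                f"{r['f1']:.2f}",
                "-" if r["fdt_aggregate"] is None else f"{r['fdt_aggregate']:.2f}",
                str(r["fp_count"]),
                "-" if r["fpr"] is None else f"{r['fpr']:.2f}",
            ]
        )
    mm = report["micro_mean"]
    rows.append(
        ["micro", f"{report['map_pooled']:.2f}", f"{mm['f1']:.2f}", "-", "-", "-"]
    )
    widths = [max(len(row[c]) for row in rows) for c in range(len(header))]
    return "\n".join(
        "  ".join(cell.rjust(w) for cell, w in zip(row, widths)) for row in rows
    )
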