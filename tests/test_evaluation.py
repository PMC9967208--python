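"""Benchmark metrics: matching, P/R/F1, AP, FDT, FP statistics, micro mean."""

import numpy as np
import pytest

from rtrepp import (
    BoundingBox,
    GroundTruthTrack,
    average_precision,
    evaluate_dataset,
    evaluate_video,
    false_positive_stats,
    first_detection_time,
    match_frame,
    match_video,
    micro_mean,
    precision_recall_f1,
)
from rtrepp.evaluation import report_table

from helpers import ap_oracle, det, video_from


def box(x, y, w, h):
    return BoundingBox(x, y, w, h)


class TestMatchFrame:
    def test_exact_match_is_tp(self):
        r = match_frame([det(0, 10, 10, 50, 50)], {"a": box(10, 10, 50, 50)})
        assert (r.n_tp, r.n_fp, r.n_fn) == (1, 0, 0)

    def test_below_threshold_is_fp_and_fn(self):
        r = match_frame([det(0, 0, 0, 10, 10)], {"a": box(6, 0, 10, 10)})
        assert (r.n_tp, r.n_fp, r.n_fn) == (0, 1, 1)

    def test_higher_confidence_claims_the_single_gt(self):
        dets = [det(0, 12, 10, 50, 50, conf=0.3), det(0, 10, 10, 50, 50, conf=0.9)]
        r = match_frame(dets, {"a": box(10, 10, 50, 50)})
        assert (r.n_tp, r.n_fp, r.n_fn) == (1, 1, 0)
        assert r.tp[0][0] == 1  # the 0.9-confidence detection

    def test_gt_coverage_mode(self):
        # detection covers 60% of the annotation but IoU is below 0.5
        r_iou = match_frame([det(0, 0, 0, 30, 10)], {"a": box(0, 0, 10, 10)})
        r_cov = match_frame(
            [det(0, 0, 0, 30, 10)], {"a": box(0, 0, 10, 10)}, mode="gt_coverage"
        )
        assert r_iou.n_tp == 0
        assert r_cov.n_tp == 1

    def test_per_frame_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            dets = [
                det(0, *rng.uniform(0, 300, 2), *rng.uniform(20, 80, 2), conf=rng.random())
                for _ in range(int(rng.integers(0, 6)))
            ]
            gts = {
                k: box(*rng.uniform(0, 300, 2), *rng.uniform(20, 80, 2))
                for k in range(int(rng.integers(0, 4)))
            }
            r = match_frame(dets, gts)
            assert r.n_tp + r.n_fp == len(dets)
            assert r.n_tp + r.n_fn == len(gts)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((2, 1, 1), (200 / 3, 200 / 3, 200 / 3)),
            ((5, 0, 0), (100.0, 100.0, 100.0)),
            ((0, 0, 0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_examples(self, counts, expected):
        assert precision_recall_f1(*counts) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(-1, 0, 0)

    def test_f1_between_min_and_max_of_p_and_r(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, fn = rng.integers(1, 50, 3)
            p, r, f1 = precision_recall_f1(int(tp), int(fp), int(fn))
            gm = (p * r) ** 0.5
            assert min(p, r) - 1e-9 <= f1 <= gm + 1e-9 <= max(p, r) + 1e-9


class TestAveragePrecision:
    def test_single_perfect_detection(self):
        gt = [GroundTruthTrack("a", {0: box(10, 10, 50, 50)})]
        v = video_from([[det(0, 10, 10, 50, 50)]])
        assert average_precision([(v, gt)]) == pytest.approx(1.0)

    def test_trailing_false_positive_does_not_reduce_ap(self):
        gt = [GroundTruthTrack("a", {0: box(10, 10, 50, 50)})]
        v = video_from(
            [[det(0, 10, 10, 50, 50, conf=0.9), det(0, 300, 300, 40, 40, conf=0.8)]]
        )
        assert average_precision([(v, gt)]) == pytest.approx(1.0)

    def test_no_ground_truth_is_an_error(self):
        v = video_from([[det(0, 10, 10, 50, 50)]])
        with pytest.raises(ValueError):
            average_precision([(v, [])])

    def test_matches_staircase_oracle_on_random_cases(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n_frames = int(rng.integers(1, 8))
            gt = [
                GroundTruthTrack(
                    k,
                    {
                        t: box(*rng.uniform(0, 250, 2), *rng.uniform(30, 90, 2))
                        for t in range(n_frames)
                        if rng.random() < 0.7
                    }
                    or {0: box(0, 0, 10, 10)},
                )
                for k in range(int(rng.integers(1, 3)))
            ]
            frames = []
            for t in range(n_frames):
                dets = []
                for track in gt:
                    if t in track.boxes and rng.random() < 0.8:
                        b = track.boxes[t]
                        dets.append(
                            det(
                                t,
                                b.x + rng.normal(0, 5),
                                b.y + rng.normal(0, 5),
                                b.w,
                                b.h,
                                conf=rng.random(),
                            )
                        )
                for _ in range(int(rng.integers(0, 3))):
                    dets.append(
                        det(t, *rng.uniform(0, 250, 2), *rng.uniform(30, 90, 2),
                            conf=rng.random())
                    )
                frames.append(dets)
            streams = [(video_from(frames or [[]]), gt)]
            assert average_precision(streams) == pytest.approx(
                ap_oracle(streams), abs=1e-12
            )

    def test_lowest_rank_fp_never_increases_ap(self):
        gt = [GroundTruthTrack("a", {0: box(10, 10, 50, 50), 1: box(10, 10, 50, 50)})]
        frames = [[det(0, 10, 10, 50, 50, conf=0.9)], [det(1, 200, 200, 40, 40, conf=0.5)]]
        base = average_precision([(video_from(frames), gt)])
        frames[1].append(det(1, 300, 300, 40, 40, conf=0.01))
        with_fp = average_precision([(video_from(frames), gt)])
        assert with_fp <= base + 1e-12

    def test_top_rank_tp_never_decreases_ap(self):
        gt = [GroundTruthTrack("a", {0: box(10, 10, 50, 50), 1: box(10, 10, 50, 50)})]
        frames = [[det(0, 200, 200, 40, 40, conf=0.5)], [det(1, 10, 10, 50, 50, conf=0.4)]]
        base = average_precision([(video_from(frames), gt)])
        frames[0].append(det(0, 10, 10, 50, 50, conf=0.99))
        with_tp = average_precision([(video_from(frames), gt)])
        assert with_tp >= base - 1e-12


class TestFirstDetectionTime:
    def _track(self, first, last):
        return GroundTruthTrack("a", {f: box(100, 100, 50, 50) for f in range(first, last)})

    def test_one_second_latency(self):
        track = self._track(10, 60)
        frames = [[] for _ in range(60)]
        frames[35] = [det(35, 100, 100, 50, 50)]
        v = video_from(frames, fps=25)
        assert first_detection_time(v, track) == pytest.approx(1.0)

    def test_first_visible_frame_detection_is_zero(self):
        track = self._track(10, 60)
        frames = [[] for _ in range(60)]
        frames[10] = [det(10, 100, 100, 50, 50)]
        assert first_detection_time(video_from(frames, fps=25), track) == 0.0

    def test_never_detected_returns_sentinel(self):
        track = self._track(10, 60)
        v = video_from([[] for _ in range(60)])
        assert first_detection_time(v, track) is None

    def test_lower_iou_threshold_never_delays_detection(self):
        track = self._track(0, 40)
        frames = [[] for _ in range(40)]
        frames[5] = [det(5, 110, 100, 50, 50)]  # partial overlap
        frames[20] = [det(20, 100, 100, 50, 50)]
        v = video_from(frames, fps=25)
        strict = first_detection_time(v, track, iou_threshold=0.9)
        loose = first_detection_time(v, track, iou_threshold=0.3)
        assert loose <= strict


class TestFalsePositiveStats:
    def _results(self, video, tracks):
        return match_video(video, tracks)

    def test_clean_negative_frames_mean_zero_fpr(self):
        tracks = [GroundTruthTrack("a", {0: box(10, 10, 50, 50)})]
        v = video_from([[det(0, 10, 10, 50, 50)], [], []])
        fp, fpr = false_positive_stats(self._results(v, tracks), tracks)
        assert (fp, fpr) == (0, 0.0)

    def test_every_negative_frame_hit_means_full_fpr(self):
        tracks = [GroundTruthTrack("a", {0: box(10, 10, 50, 50)})]
        frames = [[det(0, 10, 10, 50, 50)]] + [
            [det(t, 200, 200, 40, 40)] for t in range(1, 4)
        ]
        fp, fpr = false_positive_stats(self._results(video_from(frames), tracks), tracks)
        assert (fp, fpr) == (3, 100.0)

    def test_partial_hits(self):
        tracks = [GroundTruthTrack("a", {0: box(10, 10, 50, 50)})]
        frames = [[det(0, 10, 10, 50, 50)]] + [[] for _ in range(10)]
        for t in (2, 5, 9):
            frames[t] = [det(t, 200, 200, 40, 40)]
        fp, fpr = false_positive_stats(self._results(video_from(frames), tracks), tracks)
        assert (fp, fpr) == (3, 30.0)

    def test_no_negative_frames_gives_undefined_rate(self):
        tracks = [GroundTruthTrack("a", {0: box(10, 10, 50, 50)})]
        v = video_from([[det(0, 10, 10, 50, 50)]])
        fp, fpr = false_positive_stats(self._results(v, tracks), tracks)
        assert fpr is None

    def test_all_frames_mode(self):
        tracks = [GroundTruthTrack("a", {0: box(10, 10, 50, 50)})]
        frames = [[det(0, 10, 10, 50, 50)], [det(1, 200, 200, 40, 40)], [], []]
        _, fpr = false_positive_stats(
            self._results(video_from(frames), tracks), tracks, fpr_mode="all_frames"
        )
        assert fpr == pytest.approx(25.0)


class TestMicroMean:
    def test_pooled_counts_example(self):
        m = micro_mean([(1, 0, 0), (1, 2, 0)])
        assert m["precision"] == pytest.approx(50.0)
        assert m["recall"] == pytest.approx(100.0)
        assert m["f1"] == pytest.approx(200 / 3)

    def test_identical_videos_leave_metrics_unchanged(self):
        single = micro_mean([(3, 1, 2)])
        double = micro_mean([(3, 1, 2), (3, 1, 2)])
        assert single["f1"] == pytest.approx(double["f1"])

    def test_equals_concatenated_recount(self):
        rng = np.random.default_rng(4)
        counts = [tuple(int(v) for v in rng.integers(0, 20, 3)) for _ in range(5)]
        pooled = micro_mean(counts)
        tp, fp, fn = (sum(c[k] for c in counts) for k in range(3))
        assert (pooled["tp"], pooled["fp"], pooled["fn"]) == (tp, fp, fn)
        assert pooled["f1"] == pytest.approx(precision_recall_f1(tp, fp, fn)[2])


def test_evaluate_dataset_report_structure():
    tracks = [GroundTruthTrack("a", {t: box(100, 100, 50, 50) for t in range(5)})]
    frames = [[det(t, 100, 100, 50, 50, conf=0.9)] for t in range(5)]
    report = evaluate_dataset([(video_from(frames), tracks)])
    assert report["micro_mean"]["f1"] == pytest.approx(100.0)
    assert report["map_pooled"] == pytest.approx(100.0)
    assert report["videos"][0]["fdt_aggregate"] == 0.0
    table = report_table(report)
    assert "micro" in table and "mAP" in table
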