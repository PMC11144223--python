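"""Threshold selection, sleep-time estimation, the ratio->AHI regression,
severity banding and whole-night segmentation."""

import numpy as np
import pytest

from driven import calibrate_estimate as cal
from driven.calibrate_estimate import CalibrationModel
from driven.synthetic_psg import planted_severity
from driven.windows_labels import label_windows, make_windows


def brute_force_threshold(probs, labels):
    """Exhaustive scan with the same tie rules, written independently."""
    candidates = sorted(set(list(probs) + [0.0, 1.0]))
    rows = []
    for thr in candidates:
        pred = np.asarray(probs) >= thr
        y = np.asarray(labels)
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        rows.append((abs(p - r), -p, -thr, thr))
    return min(rows)[3]


class TestSelectThreshold:
    def test_separated_scores_pick_largest_perfect_threshold(self):
        probs = [0.9, 0.9, 0.1, 0.1]
        labels = [1, 1, 0, 0]
        assert cal.select_threshold(probs, labels) == 0.9

    def test_small_instance_matches_exhaustive_scan(self):
        probs = [0.8, 0.6, 0.7, 0.2]
        labels = [1, 1, 0, 0]
        assert cal.select_threshold(probs, labels) == brute_force_threshold(probs, labels)

    def test_property_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            probs = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert cal.select_threshold(probs, labels) == brute_force_threshold(probs, labels)

    def test_symmetric_scores_balance_precision_recall(self, rng):
        pos = 0.5 + rng.uniform(0.01, 0.49, 200)
        neg = 0.5 - rng.uniform(0.01, 0.49, 200)
        probs = np.concatenate([pos, neg])
        labels = np.array([1] * 200 + [0] * 200)
        thr = cal.select_threshold(probs, labels)
        pred = probs >= thr
        precision = (pred & (labels == 1)).sum() / pred.sum()
        recall = (pred & (labels == 1)).sum() / 200
        assert precision == pytest.approx(recall, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cal.select_threshold([0.2, 0.8], [1, 1])


class TestSleepTime:
    def test_counted_from_stride_steps(self):
        total, mask = cal.estimate_sleep_time(np.full(960, 0.9), stride_s=15.0)
        assert total == 4.0
        assert mask.all()

    def test_all_awake_gives_zero_hours(self):
        total, mask = cal.estimate_sleep_time(np.full(100, 0.1))
        assert total == 0.0 and not mask.any()

    def test_ground_truth_labels_recover_annotated_sleep(self, full_night):
        rec, ann, gt = full_night
        ds = label_windows(make_windows(rec, channels=("abdominal",)), ann)
        total, _ = cal.estimate_sleep_time(ds.sleep_label.astype(float))
        annotated = ann.total_sleep_s() / 3600.0
        # the majority rule can miscount one stride per sleep/awake transition
        n_transitions = int(np.abs(np.diff(ann.sleep_stages.astype(int))).sum())
        assert total == pytest.approx(annotated, abs=15.0 / 3600.0 * (n_transitions + 1))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cal.estimate_sleep_time([])


class TestAhiRegression:
    def test_exact_linear_data(self):
        ahis = np.array([2.0, 8.0, 20.0, 40.0])
        ratios = ahis / 100.0
        slope, intercept = cal.fit_ahi_regression(
            ratios, ahis, [planted_severity(a) for a in ahis]
        )
        assert slope == pytest.approx(100.0, abs=1e-6)
        assert intercept == pytest.approx(0.0, abs=1e-6)

    def test_balanced_classes_equal_unweighted_fit(self, rng):
        ahis = np.array([1.0, 3.0, 7.0, 12.0, 18.0, 25.0, 35.0, 50.0])
        ratios = ahis / 90.0 + rng.normal(0, 0.005, 8)
        slope, intercept = cal.fit_ahi_regression(
            ratios, ahis, [planted_severity(a) for a in ahis]
        )
        unweighted = np.polyfit(ratios, ahis, 1)
        assert slope == pytest.approx(unweighted[0], abs=1e-9)
        assert intercept == pytest.approx(unweighted[1], abs=1e-9)

    def test_duplicated_class_downweighted_to_deduplicated_fit(self):
        """Closed-form check: repeating one severe patient 5x with 1/count
        weights must reproduce the fit on the de-duplicated set."""
        base_ahis = [2.0, 8.0, 20.0, 40.0]
        base_ratios = [0.03, 0.1, 0.22, 0.38]
        dup_ahis = base_ahis + [40.0] * 4
        dup_ratios = base_ratios + [0.38] * 4
        a = cal.fit_ahi_regression(
            base_ratios, base_ahis, [planted_severity(x) for x in base_ahis]
        )
        b = cal.fit_ahi_regression(
            dup_ratios, dup_ahis, [planted_severity(x) for x in dup_ahis]
        )
        assert a == pytest.approx(b, abs=1e-9)

    def test_degenerate_ratios_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cal.fit_ahi_regression([0.1, 0.1], [5.0, 10.0], ["mild", "mild"])


class TestPredictAndSeverity:
    def test_prediction_arithmetic_and_clipping(self):
        calib = CalibrationModel(0.5, 100.0, 0.0)
        assert cal.predict_ahi(calib, 0.0) == 0.0
        assert cal.predict_ahi(calib, 0.2) == pytest.approx(20.0)
        calib_neg = CalibrationModel(0.5, 100.0, -5.0)
        assert cal.predict_ahi(calib_neg, 0.01) == 0.0

    def test_monotone_in_ratio(self):
        calib = CalibrationModel(0.5, 80.0, -1.0)
        ratios = np.linspace(0, 1, 50)
        preds = [cal.predict_ahi(calib, r) for r in ratios]
        assert np.all(np.diff(preds) >= 0)

    @pytest.mark.parametrize(
        "ahi,expected",
        [
            (0.0, "healthy"), (4.9, "healthy"),
            (5.0, "mild"), (14.9, "mild"),
            (15.0, "moderate"), (29.9, "moderate"),
            (30.0, "severe"), (31.0, "severe"), (100.0, "severe"),
        ],
    )
    def test_aasm_bands_left_closed(self, ahi, expected):
        assert cal.severity_class(ahi) == expected

    def test_negative_ahi_rejected(self):
        with pytest.raises(ValueError):
            cal.severity_class(-1.0)


class TestSegmentNight:
    def test_all_awake(self):
        states, intervals = cal.segment_night(np.full(10, 0.9), np.zeros(10, bool), 0.5)
        assert states == ["awake"] * 10
        assert intervals == []

    def test_three_consecutive_positives_merge_to_sixty_seconds(self):
        probs = np.array([0.1, 0.9, 0.9, 0.9, 0.1])
        states, intervals = cal.segment_night(probs, np.ones(5, bool), 0.5)
        assert states == ["normal", "event", "event", "event", "normal"]
        assert intervals == [(15.0, 75.0)]

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            cal.segment_night(np.ones(5), np.ones(4, bool), 0.5)

    def test_awake_breaks_event_runs(self):
        probs = np.full(4, 0.9)
        mask = np.array([True, False, True, True])
        states, intervals = cal.segment_night(probs, mask, 0.5)
        assert states[1] == "awake"
        assert len(intervals) == 2


class TestEstimateFromProbs:
    def test_zero_sleep_flagged_undetermined(self):
        calib = CalibrationModel(0.5, 100.0, 0.0)
        report = cal.estimate_from_probs(np.ones(10), np.zeros(10), calib, "P")
        assert report.severity == "undetermined"
        assert "no predicted sleep" in report.flags

    def test_oracle_labels_recover_planted_ahi(self, full_night):
        """Ground-truth labels as probabilities, calibrated on the same
        night's relation, land within 2 events/h of the planted AHI."""
        rec, ann, gt = full_night
        ds = label_windows(make_windows(rec, channels=("abdominal",)), ann)
        ratio = cal.positive_ratio(ds.event_label.astype(float), ds.sleep_label.astype(float), 0.5)
        slope = gt.planted_ahi / ratio
        calib = CalibrationModel(0.5, slope, 0.0)
        report = cal.estimate_from_probs(
            ds.event_label.astype(float), ds.sleep_label.astype(float), calib, "P"
        )
        assert report.ahi_estimate == pytest.approx(gt.planted_ahi, abs=2.0)
        assert report.positive_ratio == pytest.approx(ratio)
        assert len(report.timeline) == len(ds)

    def test_segmentation_plot_written(self, tmp_path, rng):
        pytest.importorskip("matplotlib")
        calib = CalibrationModel(0.5, 90.0, 0.0)
        report = cal.estimate_from_probs(rng.random(200), rng.random(200), calib, "P")
        cal.plot_segmentation(report, tmp_path / "night.png")
        assert (tmp_path / "night.png").stat().st_size > 0

    def test_report_consistency_invariants(self, full_night):
        rec, ann, _ = full_night
        ds = label_windows(make_windows(rec, channels=("abdominal",)), ann)
        calib = CalibrationModel(0.5, 90.0, -0.5)
        report = cal.estimate_from_probs(
            ds.event_label.astype(float), ds.sleep_label.astype(float), calib, "P"
        )
        assert report.positive_ratio == pytest.approx(
            report.n_positive_windows / report.n_sleep_windows
        )
        assert report.ahi_estimate >= 0
        assert report.severity == cal.severity_class(report.ahi_estimate)
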