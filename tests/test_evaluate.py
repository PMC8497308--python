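"""ROC/AUC, alarm merging, operating point, event-sensitivity arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teevae.evaluate import (DegenerateLabelsError, auc_concordance,
                             event_sensitivity, frame_labels, merge_alarms,
                             operating_point, roc)
from teevae.io import AnnotationTrack, ValidityMask
from teevae.postprocess import DetectionSeries


def auc_pairwise(scores, labels):
    """O(n^2) Mann-Whitney oracle: concordant pairs count 1, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def make_series(score, valid=None, fps=38.0):
    score = np.asarray(score, float)
    if valid is None:
        valid = np.isfinite(score)
    return DetectionSeries(score, score, score, np.asarray(valid, bool), fps)


class TestFrameLabels:
    def test_counting_min_grade1(self):
        track = AnnotationTrack([(20, 70, "grade2")], 200)
        labels, excluded = frame_labels(track, min_grade=1)
        assert labels.sum() == 50
        assert (~labels & ~excluded).sum() == 150

    def test_grade1_excluded_at_min_grade2(self):
        track = AnnotationTrack([(20, 70, "grade2"), (100, 130, "grade1")], 200)
        labels, excluded = frame_labels(track, min_grade=2)
        assert labels.sum() == 50
        assert excluded.sum() == 30
        assert (~labels & ~excluded).sum() == 120

    def test_empty_track_all_negative(self):
        labels, excluded = frame_labels(AnnotationTrack([], 50), 1)
        assert not labels.any() and not excluded.any()


class TestRoc:
    def test_perfect_scores(self):
        labels = np.array([0, 0, 1, 1, 0, 1], bool)
        res = roc(make_series(labels.astype(float)), labels)
        assert res.auc == 1.0

    def test_anti_perfect_scores(self):
        labels = np.array([0, 0, 1, 1, 0, 1], bool)
        res = roc(make_series(1.0 - labels), labels)
        assert res.auc == 0.0

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(5):
            scores = rng.integers(0, 5, 20).astype(float)  # heavy ties
            labels = rng.integers(0, 2, 20).astype(bool)
            if labels.all() or not labels.any():
                continue
            res = roc(make_series(scores), labels)
            oracle = auc_pairwise(scores, labels)
            assert res.auc == pytest.approx(oracle, abs=1e-12)
            assert auc_concordance(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200).astype(bool)
        res = roc(make_series(scores), labels)
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100).astype(bool)
        res = roc(make_series(scores), labels)
        assert np.all(np.diff(res.tpr) >= 0)
        assert np.all(np.diff(res.fpr) >= 0)

    def test_excluded_frames_dropped(self):
        scores = np.array([0.0, 1.0, 0.5, 0.2])
        labels = np.array([0, 1, 1, 0], bool)
        excluded = np.array([0, 0, 1, 0], bool)
        res = roc(make_series(scores), labels, excluded)
        assert res.n_pos == 1 and res.n_neg == 2

    def test_degenerate_labels(self):
        with pytest.raises(DegenerateLabelsError):
            roc(make_series([1.0, 2.0]), np.array([1, 1], bool))


class TestMergeAlarms:
    def test_example_gap(self):
        events = merge_alarms([10, 30, 100], merge_gap_frames=38)
        assert [(e.start_frame, e.end_frame) for e in events] == [(10, 30), (100, 100)]

    def test_empty(self):
        assert merge_alarms([]) == []

    def test_idempotent_on_random_sets(self, rng):
        for _ in range(10):
            frames = np.unique(rng.integers(0, 2000, 60))
            once = merge_alarms(frames, 38)
            # merging the frames covered by the merged events reproduces them
            covered = [f for e in once
                       for f in range(e.start_frame, e.end_frame + 1)]
            again = merge_alarms(covered, 38)
            assert [(e.start_frame, e.end_frame) for e in once] == \
                   [(e.start_frame, e.end_frame) for e in again]

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 3000), min_size=0, max_size=80),
           st.integers(1, 100))
    def test_event_count_equals_gap_count(self, frames, gap):
        """Events = 1 + number of adjacent gaps exceeding the merge gap."""
        uniq = sorted(set(frames))
        events = merge_alarms(uniq, gap)
        if not uniq:
            assert events == []
            return
        expected = 1 + sum(b - a > gap for a, b in zip(uniq, uniq[1:]))
        assert len(events) == expected
        # events cover every supra-threshold frame and are disjoint
        assert all(e.start_frame <= e.end_frame for e in events)
        assert all(events[i + 1].start_frame - events[i].end_frame > gap
                   for i in range(len(events) - 1))

    def test_matches_one_pass_oracle(self, rng):
        frames = np.unique(rng.integers(0, 500, 40))
        events = merge_alarms(frames, 10)
        # oracle: count boundaries where the gap exceeds the merge gap
        expected = 1 + int(np.sum(np.diff(frames) > 10))
        assert len(events) == expected


class TestEventSensitivity:
    @pytest.mark.parametrize("det,total,expected", [
        (124, 180, 69), (28, 39, 72), (17, 180, 9),
        (0, 10, 0), (10, 10, 100), (1, 200, 1),
    ])
    def test_rounded_percentages(self, det, total, expected):
        assert event_sensitivity(det, total) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            event_sensitivity(1, 0)
        with pytest.raises(ValueError):
            event_sensitivity(5, 3)


class TestOperatingPoint:
    def _track(self, intervals, n=2000):
        return AnnotationTrack(intervals, n)

    def test_zero_score_target_unreachable(self):
        track = self._track([(100, 300, "grade2")])
        series = make_series(np.zeros(2000))
        op = operating_point(series, track)
        assert not op.target_reached
        assert op.event_sensitivity == 0.0

    def test_clean_detection(self):
        score = np.zeros(2000)
        score[150:250] = 50.0
        score[1000:1100] = 60.0
        track = self._track([(140, 400, "grade2"), (995, 1200, "grade3")])
        op = operating_point(make_series(score), track)
        assert op.target_reached
        assert op.event_sensitivity == 1.0
        assert op.false_alarm_count == 0

    def test_false_alarm_counting(self):
        score = np.zeros(4000)
        score[150:250] = 50.0    # inside the event
        score[2000:2010] = 50.0  # an isolated false alarm
        score[3000:3010] = 50.0  # another, > 38 frames away
        track = self._track([(140, 400, "grade2")], n=4000)
        op = operating_point(make_series(score), track)
        assert op.false_alarm_count == 2
        minutes = 4000 / 38.0 / 60.0
        assert op.false_alarms_per_min == pytest.approx(2 / minutes)

    def test_alarm_overlapping_truth_not_false(self):
        score = np.zeros(2000)
        score[150:500] = 50.0  # extends beyond the event end
        track = self._track([(140, 400, "grade2")])
        op = operating_point(make_series(score), track)
        assert op.false_alarm_count == 0

    def test_detection_must_fall_in_response_window(self):
        # score rises only 5 s after the event starts: too late at 3 s
        score = np.zeros(2000)
        score[500 + 190: 900] = 50.0
        track = self._track([(500, 900, "grade3")])
        op = operating_point(make_series(score), track)
        assert not op.target_reached

    def test_lower_target_never_more_false_alarms(self, event_scene):
        from teevae.pipeline import detect
        series = detect(event_scene.video, event_scene.annotations)
        rates = []
        for target in (0.9, 0.5):
            op = operating_point(series, event_scene.annotations,
                                 target_event_sensitivity=target)
            rates.append(op.false_alarms_per_min)
        assert rates[1] <= rates[0]
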