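"""Detector scoring: frame-level ROC/AUC, alarm merging, operating points.

The score series is compared frame-by-frame against the graded visible-air
reference.  With ``min_grade=2``, grade-1 frames are removed from the
analysis entirely (neither positives nor negatives); frames with sporadic
isolated bubbles carry no grade interval and count as non-targets.  Alarm
events merge supra-threshold frames less than one second (38 frames) apart,
and the operating point forces a target event sensitivity (90% of events
detected within a 3-s response window) while counting false alarms per
minute of valid analyzed video.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationTrack, ValidityMask
from .postprocess import DetectionSeries

DEFAULT_MERGE_GAP = 38     # frames (~1 s at 38 fps)
DEFAULT_RESPONSE_S = 3.0
DEFAULT_TARGET_SENSITIVITY = 0.9


class DegenerateLabelsError(ValueError):
    """ROC undefined: the analyzed frames contain no positives or no negatives."""


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class AlarmEvent:
    """A maximal merged run of supra-threshold frames."""

    start_frame: int
    end_frame: int  # inclusive index of the last supra-threshold frame


@dataclass
class OperatingPoint:
    threshold: float
    event_sensitivity: float
    n_events: int
    n_detected: int
    false_alarms_per_min: float
    false_alarm_count: int
    valid_minutes: float
    response_window_s: float
    target_reached: bool


def frame_labels(track: AnnotationTrack, min_grade: int = 1
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame binary target labels plus an exclusion mask.

    Returns ``(labels, excluded)``: frames inside grade >= min_grade
    intervals are positives; with ``min_grade=2`` the grade-1 frames are
    excluded from the analysis altogether; everything else is negative.
    """
    labels = np.zeros(track.total_frames, dtype=bool)
    excluded = np.zeros(track.total_frames, dtype=bool)
    for s, e, g in track.grade_intervals(min_grade=1):
        if g >= min_grade:
            labels[s:e] = True
        else:
            excluded[s:e] = True
    return labels, excluded


def auc_concordance(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance statistic, ties counting one half.

    O(n log n) via ranking; equals the pairwise O(n^2) count exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("need at least one positive and one negative")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    i = 0
    rank = 1.0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = (rank + rank + (j - i)) / 2.0
        rank += j - i + 1
        i = j + 1
    rank_sum = ranks[labels].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc(score: DetectionSeries | np.ndarray, labels: np.ndarray,
        excluded: np.ndarray | None = None) -> RocResult:
    """ROC over all distinct score thresholds on the analyzable frames.

    Frames that are excluded, invalid, or carry no score (NaN) are dropped.
    AUC is the trapezoidal area, which equals the concordance statistic with
    ties counted one half.
    """
    if isinstance(score, DetectionSeries):
        values = score.score
        analyzable = score.score_valid.copy()
    else:
        values = np.asarray(score, dtype=float)
        analyzable = np.isfinite(values)
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != len(values):
        raise ValueError("labels length mismatch")
    if excluded is not None:
        analyzable &= ~np.asarray(excluded, dtype=bool)
    s = values[analyzable]
    y = labels[analyzable]
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"degenerate labels: {n_pos} positives, {n_neg} negatives"
        )
    # sweep thresholds from high to low over distinct score values
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(y_sorted)[cut]
    fp = np.cumsum(~y_sorted)[cut]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.r_[np.inf, s_sorted[cut]]
    return RocResult(thresholds, tpr, fpr, auc, n_pos, n_neg)


def merge_alarms(supra_frames, merge_gap_frames: int = DEFAULT_MERGE_GAP
                 ) -> list[AlarmEvent]:
    """Merge supra-threshold frames at most ``merge_gap_frames`` apart into
    single alarm events."""
    frames = sorted(int(f) for f in supra_frames)
    if not frames:
        return []
    events = []
    start = prev = frames[0]
    for f in frames[1:]:
        if f - prev <= merge_gap_frames:
            prev = f
        else:
            events.append(AlarmEvent(start, prev))
            start = prev = f
    events.append(AlarmEvent(start, prev))
    return events


def event_sensitivity(n_detected: int, n_total: int) -> int:
    """Percentage of events detected, rounded to the nearest integer
    (ties away from zero)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_detected <= n_total:
        raise ValueError("need 0 <= n_detected <= n_total")
    return int(math.floor(100.0 * n_detected / n_total + 0.5))


def operating_point(score: DetectionSeries, track: AnnotationTrack,
                    min_grade: int = 1,
                    target_event_sensitivity: float = DEFAULT_TARGET_SENSITIVITY,
                    response_s: float = DEFAULT_RESPONSE_S,
                    merge_gap_frames: int = DEFAULT_MERGE_GAP) -> OperatingPoint:
    """Threshold forcing the target event sensitivity; false alarms per minute.

    An event counts as detected at threshold t if any scored frame within
    ``response_s`` seconds of its start exceeds t.  The operating threshold
    is the largest candidate (a distinct score value, or 0) at which the
    detected fraction still reaches the target; if even threshold 0 falls
    short, the maximum achievable sensitivity is reported with
    ``target_reached=False``.  False alarms are merged supra-threshold alarm
    events overlapping no visible-air interval of any grade, per minute of
    valid analyzed video.
    """
    events = track.grade_intervals(min_grade=min_grade)
    if not events:
        raise ValueError("no annotated events of the requested grade")
    n_frames = len(score.score)
    window = int(round(response_s * score.fps))

    event_best = np.empty(len(events))
    for i, (s, e, g) in enumerate(events):
        hi = min(s + window + 1, n_frames)
        seg = score.score[s:hi][score.score_valid[s:hi]]
        event_best[i] = seg.max() if len(seg) else -np.inf

    finite = score.score[score.score_valid]
    candidates = np.unique(np.r_[finite, 0.0])[::-1]  # high to low, includes 0
    n_events = len(events)
    threshold = None
    for t in candidates:
        frac = float((event_best > t).sum()) / n_events
        if frac >= target_event_sensitivity:
            threshold = float(t)
            break
    if threshold is None:
        threshold = 0.0
        reached = False
    else:
        reached = True
    n_detected = int((event_best > threshold).sum())
    sens = n_detected / n_events

    supra = np.nonzero(score.score_valid & (score.score > threshold))[0]
    alarms = merge_alarms(supra, merge_gap_frames)
    air_iv = track.grade_intervals(min_grade=1)
    false_count = 0
    for al in alarms:
        overlaps = any(al.start_frame < e and al.end_frame >= s
                       for s, e, g in air_iv)
        if not overlaps:
            false_count += 1
    valid_minutes = float(score.score_valid.sum()) / score.fps / 60.0
    rate = false_count / valid_minutes if valid_minutes > 0 else float("inf")
    return OperatingPoint(threshold, sens, n_events, n_detected, rate,
                          false_count, valid_minutes, response_s, reached)


def k_sweep_table(results: dict[float, float]) -> pd.DataFrame:
    """Arrange per-k AUCs as a table (columns ``k``, ``auc``)."""
    ks = sorted(results)
    return pd.DataFrame({"k": ks, "auc": [results[k] for k in ks]})
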