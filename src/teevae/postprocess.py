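"""Smoothing and noise-floor correction of the raw air-pixel count series.

The per-frame count of air-classified pixels is median-filtered (window 140
frames, robust to short outliers) and a per-segment noise floor — the
nearest-rank 15% quantile over the first 140 frames after each detector
reinitialization — is subtracted, clipping at zero.  Frames excluded by the
validity mask or produced by cold statistics are skipped (not zero-filled) in
both windows and carry no score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .background import nearest_rank_quantile
from .io import ValidityMask

DEFAULT_MEDIAN_WINDOW = 140
DEFAULT_FLOOR_WINDOW = 140
DEFAULT_FLOOR_QUANTILE = 0.15


@dataclass
class DetectionSeries:
    """Raw, smoothed and floor-corrected per-frame detection series.

    ``score`` is NaN wherever the frame is excluded (invalid or cold
    statistics); ``score_valid`` marks the frames that enter ROC analysis.
    """

    raw_counts: np.ndarray
    smoothed: np.ndarray
    score: np.ndarray
    score_valid: np.ndarray
    fps: float
    reinit_frames: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.raw_counts)


def _lower_median(window: np.ndarray) -> float:
    """Order statistic floor((n+1)/2) (1-based): the lower median.

    Keeps the statistic integer-valued on integer counts for even windows.
    """
    n = len(window)
    k = (n + 1) // 2
    return float(np.partition(window, k - 1)[k - 1])


def rolling_median(raw: np.ndarray, window: int = DEFAULT_MEDIAN_WINDOW,
                   alignment: str = "trailing") -> np.ndarray:
    """Rolling lower-median; trailing (causal) by default.

    Positions with fewer than ``window`` available samples use all available
    ones.  ``alignment='centered'`` is offered for offline replication.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    out = np.empty(n)
    if alignment == "trailing":
        for i in range(n):
            lo = max(0, i - window + 1)
            out[i] = _lower_median(raw[lo:i + 1])
    elif alignment == "centered":
        half = window // 2
        for i in range(n):
            lo = max(0, i - half)
            hi = min(n, i + window - half)
            out[i] = _lower_median(raw[lo:hi])
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    return out


def noise_floor(smoothed: np.ndarray, window: int = DEFAULT_FLOOR_WINDOW,
                quantile: float = DEFAULT_FLOOR_QUANTILE) -> float:
    """Noise floor of a post-reinitialization segment: the nearest-rank
    quantile of its first ``min(window, len)`` values."""
    smoothed = np.asarray(smoothed, dtype=float)
    if len(smoothed) == 0:
        raise ValueError("need at least one frame after reinitialization")
    return nearest_rank_quantile(smoothed[:min(window, len(smoothed))], quantile)


def build_score(raw_counts: np.ndarray, validity: ValidityMask,
                warm: np.ndarray | None = None, fps: float = 38.0,
                median_window: int = DEFAULT_MEDIAN_WINDOW,
                floor_window: int = DEFAULT_FLOOR_WINDOW,
                floor_quantile: float = DEFAULT_FLOOR_QUANTILE,
                alignment: str = "trailing",
                floor_source: str = "smoothed") -> DetectionSeries:
    """Compose smoothing and noise-floor correction per reinit segment.

    Each segment delimited by reinitialization frames is processed
    independently: its usable frames (valid and warm) are median-smoothed,
    the segment's floor is taken over its first ``floor_window`` usable
    frames, subtracted, and clipped at zero.  ``floor_source`` selects
    whether the floor quantile is computed on the smoothed series (default)
    or the raw counts.
    """
    raw_counts = np.asarray(raw_counts, dtype=float)
    n = len(raw_counts)
    if len(validity) != n:
        raise ValueError(f"validity mask length {len(validity)} != series {n}")
    if warm is None:
        warm = np.ones(n, dtype=bool)
    warm = np.asarray(warm, dtype=bool)
    if len(warm) != n:
        raise ValueError("warm flag length mismatch")

    usable = validity.valid & warm
    smoothed = np.full(n, np.nan)
    score = np.full(n, np.nan)

    bounds = [0, *[r for r in validity.reinit_frames if 0 < r < n], n]
    for lo, hi in zip(bounds, bounds[1:]):
        idx = np.nonzero(usable[lo:hi])[0] + lo
        if len(idx) == 0:
            continue
        seg_raw = raw_counts[idx]
        seg_smooth = rolling_median(seg_raw, median_window, alignment)
        floor_series = seg_smooth if floor_source == "smoothed" else seg_raw
        floor = noise_floor(floor_series, floor_window, floor_quantile)
        smoothed[idx] = seg_smooth
        score[idx] = np.maximum(seg_smooth - floor, 0.0)

    return DetectionSeries(raw_counts, smoothed, score, usable & np.isfinite(score),
                           fps, validity.reinit_frames)
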