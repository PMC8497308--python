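"""Per-pixel, per-phase rolling Gaussian background model with outlier test.

For every pixel and every cardiac phase segment, the last 30 intensity
samples observed at that phase form a hard window from which a rolling mean
mu and population standard deviation sigma are computed.  To suppress
spurious detections in dark, low-variance regions, sigma is floored at the
65% quantile (nearest-rank) of the sigma image.  A pixel is air iff

    I - mu > k * sigma_floored     (strict, one-sided bright-outlier test)

with sensitivity parameter k = 3 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DEFAULT_WINDOW = 30
DEFAULT_K = 3.0
DEFAULT_SIGMA_QUANTILE = 0.65
DEFAULT_WARMUP_MIN = 15  # half the window; detections only after this many samples


@dataclass
class DetectionFrameResult:
    """Outcome of the outlier test on one frame."""

    frame_index: int
    phase: int
    warm: bool
    air_pixel_count: int
    air_mask: np.ndarray | None = None


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """The ceil(q*N)-th order statistic (1-based); q in (0, 1]."""
    flat = np.asarray(values).ravel()
    n = flat.size
    if n == 0:
        raise ValueError("empty sample")
    k = max(1, math.ceil(q * n))
    return float(np.partition(flat, k - 1)[k - 1])


def sigma_floor(sigma_image: np.ndarray,
                quantile: float = DEFAULT_SIGMA_QUANTILE) -> np.ndarray:
    """Floor the sigma image elementwise at its nearest-rank quantile."""
    q = nearest_rank_quantile(sigma_image, quantile)
    return np.maximum(sigma_image, q)


def classify_air(frame: np.ndarray, mu: np.ndarray, sigma_floored: np.ndarray,
                 k: float = DEFAULT_K) -> np.ndarray:
    """Boolean air mask: intensity exceeds the mean by more than k sigma."""
    if k <= 0:
        raise ValueError("k must be positive")
    return frame.astype(np.float64) - mu > k * sigma_floored


class PhaseStatistics:
    """Ring buffers of the last ``window`` frames per cardiac phase segment.

    Rolling mean and population sigma are maintained exactly through integer
    sums over the uint8 buffer, so ``mean``/``std`` equal a direct recompute
    of the buffered samples to floating-point rounding.
    """

    def __init__(self, shape: tuple[int, int], n_phases: int = 15,
                 window: int = DEFAULT_WINDOW,
                 warmup_min_samples: int = DEFAULT_WARMUP_MIN):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.shape = shape
        self.n_phases = n_phases
        self.window = window
        self.warmup_min_samples = warmup_min_samples
        self._buf = np.zeros((n_phases, window) + shape, dtype=np.uint8)
        self._sum = np.zeros((n_phases,) + shape, dtype=np.int64)
        self._sumsq = np.zeros((n_phases,) + shape, dtype=np.int64)
        self._count = np.zeros(n_phases, dtype=int)
        self._head = np.zeros(n_phases, dtype=int)

    def reset(self) -> None:
        """Discard all buffered samples (reinitialization)."""
        self._buf.fill(0)
        self._sum.fill(0)
        self._sumsq.fill(0)
        self._count.fill(0)
        self._head.fill(0)

    def sample_count(self, phase: int) -> int:
        return int(self._count[phase])

    def is_warm(self, phase: int) -> bool:
        return self.sample_count(phase) >= self.warmup_min_samples

    def update(self, frame: np.ndarray, phase: int) -> None:
        """Append a frame to the given phase's window, evicting the oldest."""
        frame = np.asarray(frame)
        if frame.shape != self.shape:
            raise ValueError(f"frame shape {frame.shape} != {self.shape}")
        if frame.dtype != np.uint8:
            frame = np.clip(np.rint(np.asarray(frame, dtype=float)), 0, 255
                            ).astype(np.uint8)
        h = self._head[phase]
        if self._count[phase] == self.window:
            old = self._buf[phase, h].astype(np.int64)
            self._sum[phase] -= old
            self._sumsq[phase] -= old * old
        else:
            self._count[phase] += 1
        self._buf[phase, h] = frame
        f64 = frame.astype(np.int64)
        self._sum[phase] += f64
        self._sumsq[phase] += f64 * f64
        self._head[phase] = (h + 1) % self.window

    def mean(self, phase: int) -> np.ndarray:
        c = self._count[phase]
        if c == 0:
            raise ValueError(f"phase {phase} has no samples")
        return self._sum[phase] / c

    def std(self, phase: int) -> np.ndarray:
        """Population standard deviation (divide by count) of the buffer."""
        c = self._count[phase]
        if c == 0:
            raise ValueError(f"phase {phase} has no samples")
        mu = self._sum[phase] / c
        var = self._sumsq[phase] / c - mu * mu
        return np.sqrt(np.maximum(var, 0.0))

    def buffered(self, phase: int) -> np.ndarray:
        """The raw buffered samples of a phase, oldest first (for auditing)."""
        c = self._count[phase]
        h = self._head[phase]
        if c < self.window:
            return self._buf[phase, :c].copy()
        order = (np.arange(self.window) + h) % self.window
        return self._buf[phase, order].copy()

    def classify(self, frame: np.ndarray, phase: int, frame_index: int = -1,
                 k: float = DEFAULT_K,
                 sigma_quantile: float = DEFAULT_SIGMA_QUANTILE,
                 keep_mask: bool = False) -> DetectionFrameResult:
        """Run the outlier test against the current statistics of ``phase``.

        Returns a cold (count 0, ``warm=False``) result before the phase has
        accumulated ``warmup_min_samples`` frames.
        """
        if not self.is_warm(phase):
            return DetectionFrameResult(frame_index, phase, False, 0,
                                        np.zeros(self.shape, bool) if keep_mask else None)
        mu = self.mean(phase)
        sig = sigma_floor(self.std(phase), sigma_quantile)
        mask = classify_air(frame, mu, sig, k)
        return DetectionFrameResult(frame_index, phase, True, int(mask.sum()),
                                    mask if keep_mask else None)
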