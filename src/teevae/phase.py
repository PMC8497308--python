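"""Cardiac phase estimation from the ROI mean-intensity signal.

The spatial mean grayscale over a rectangular region reflects cardiac
periodicity (chamber filling darkens the region cyclically).  The signal is
high-pass filtered (2nd-order Butterworth, critical frequency 5 Hz by
default), delay-embedded into 5-vectors with a 3-frame lag (a Takens state
reconstruction), and each frame is assigned to one of 15 cardiac phase
segments by nearest-reference matching against one stored reference cycle.

Note on the default cutoff: a 5 Hz high-pass lies above the cardiac
fundamental (~1-2 Hz), so at ~38 fps the filter passes only the upper
harmonics of the cardiac signal plus fast transients.  This is the published
configuration and is kept as the default; the cutoff, order and pass
direction are parameters for users who prefer a fundamental-preserving band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import FrameSequence, RegionOfInterest

EMBED_DELAY = 3   # frames between embedding taps
EMBED_DIM = 5     # taps per embedding vector
N_SEGMENTS = 15   # cardiac phase segments per cycle
WARMUP = EMBED_DELAY * (EMBED_DIM - 1)  # first frame with a defined embedding


class InitializationError(RuntimeError):
    """Raised when no cardiac period can be extracted (e.g. flat signal)."""


@dataclass
class IntensitySignal:
    """Mean grayscale over the ROI, one value per frame."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class FilteredSignal:
    """High-pass-filtered intensity signal {x_n} plus its filter design."""

    x: np.ndarray
    fps: float
    order: int = 2
    critical_hz: float = 5.0


@dataclass
class ReferenceCycle:
    """One cardiac period of embedding vectors split into phase segments.

    ``vectors[i]`` is the embedding of the i-th frame of the cycle;
    ``segment_of[i] = floor(N_SEGMENTS * i / period_frames)`` partitions the
    cycle into 15 contiguous runs whose lengths differ by at most one.
    """

    vectors: np.ndarray        # (period_frames, EMBED_DIM)
    segment_of: np.ndarray     # (period_frames,) ints in [0, N_SEGMENTS)
    period_frames: int
    start_frame: int           # frame index of vectors[0] in the source signal


def mean_intensity_signal(seq: FrameSequence,
                          roi: RegionOfInterest | None = None) -> IntensitySignal:
    """Spatial mean of the ROI per frame (the raw cardiac signal)."""
    if roi is None:
        roi = RegionOfInterest.centered(seq.width, seq.height)
    roi.validate_within(seq.width, seq.height)
    ys, xs = roi.slices()
    values = seq.frames[:, ys, xs].mean(axis=(1, 2), dtype=np.float64)
    return IntensitySignal(values, seq.fps)


def butter_highpass(fps: float, critical_hz: float = 5.0,
                    order: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Digital Butterworth high-pass coefficients (b, a) via bilinear transform."""
    if critical_hz >= fps / 2.0:
        raise ValueError(
            f"critical frequency {critical_hz} Hz >= Nyquist {fps / 2.0} Hz"
        )
    return sps.butter(order, critical_hz, btype="highpass", fs=fps)


def highpass_filter(sig: IntensitySignal, critical_hz: float = 5.0,
                    order: int = 2, zero_phase: bool = False) -> FilteredSignal:
    """High-pass the cardiac signal; causal by default (live monitoring).

    ``zero_phase=True`` applies forward-backward filtering for offline use.
    The causal filter has exactly zero DC gain and -3 dB magnitude at the
    critical frequency.
    """
    b, a = butter_highpass(sig.fps, critical_hz, order)
    if zero_phase:
        x = sps.filtfilt(b, a, sig.values)
    else:
        # start from the steady-state response to the first sample's level so
        # the DC step at the segment boundary produces no startup transient
        zi = sps.lfilter_zi(b, a) * sig.values[0]
        x, _ = sps.lfilter(b, a, sig.values, zi=zi)
    return FilteredSignal(np.asarray(x), sig.fps, order, critical_hz)


def embed(x: np.ndarray, n: int) -> np.ndarray:
    """Delay-embedding vector (x_{n-12}, x_{n-9}, x_{n-6}, x_{n-3}, x_n)."""
    if n < WARMUP:
        raise ValueError(f"embedding undefined for n={n} < {WARMUP}")
    if n >= len(x):
        raise ValueError(f"n={n} beyond signal of length {len(x)}")
    idx = n - EMBED_DELAY * np.arange(EMBED_DIM - 1, -1, -1)
    return np.asarray(x)[idx]


def embed_all(x: np.ndarray) -> np.ndarray:
    """Embedding vectors for every frame n >= 12, as an (n-12, 5) matrix row
    ``i`` being the embedding at frame ``i + 12``."""
    x = np.asarray(x)
    if len(x) <= WARMUP:
        return np.empty((0, EMBED_DIM))
    cols = [x[WARMUP - EMBED_DELAY * j: len(x) - EMBED_DELAY * j]
            for j in range(EMBED_DIM - 1, -1, -1)]
    return np.stack(cols, axis=1)


def estimate_period(x: np.ndarray, fps: float,
                    period_band_s: tuple[float, float] = (0.4, 2.0),
                    min_autocorr: float = 0.2) -> int:
    """Cardiac period in frames: the autocorrelation-maximizing lag within a
    physiologic band (default 0.4-2.0 s, i.e. 30-150 bpm)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    var = float(np.dot(x, x))
    if var < 1e-12 * max(len(x), 1):
        raise InitializationError("flat signal: no cardiac periodicity")
    lag_min = max(2, int(round(period_band_s[0] * fps)))
    lag_max = int(round(period_band_s[1] * fps))
    lag_max = min(lag_max, len(x) - 1)
    if lag_max < lag_min:
        raise InitializationError("signal too short for the period band")
    full = np.correlate(x, x, mode="full")[len(x) - 1:]
    r = full / full[0]
    band = r[lag_min:lag_max + 1]
    best = int(np.argmax(band)) + lag_min
    if r[best] < min_autocorr:
        raise InitializationError(
            f"no autocorrelation peak >= {min_autocorr} in the period band"
        )
    return best


def segment_map(period_frames: int, n_segments: int = N_SEGMENTS) -> np.ndarray:
    """Assign cycle position i to segment floor(n_segments * i / period)."""
    i = np.arange(period_frames)
    return (n_segments * i) // period_frames


def extract_reference_cycle(x: FilteredSignal | np.ndarray, start_frame: int = 0,
                            fps: float | None = None,
                            window_s: float = 5.0,
                            period_band_s: tuple[float, float] = (0.4, 2.0),
                            ) -> ReferenceCycle:
    """Extract one cardiac period of embedding vectors from ``start_frame``.

    The period is estimated on an initialization window (default 5 s, at
    least two slowest-band cycles); the reference vectors are the embeddings
    of the first full period after the embedding warm-up.  Raises
    :class:`InitializationError` on flat input; the caller may retry later.
    """
    if isinstance(x, FilteredSignal):
        fps = x.fps
        x = x.x
    if fps is None:
        raise ValueError("fps required when passing a bare array")
    x = np.asarray(x, dtype=float)
    lag_max = int(round(period_band_s[1] * fps))
    win = max(int(round(window_s * fps)), WARMUP + 2 * lag_max + 1)
    window = x[start_frame: start_frame + win]
    period = estimate_period(window, fps, period_band_s)
    first = start_frame + WARMUP
    if first + period > len(x):
        raise InitializationError("not enough frames after warm-up for one period")
    vectors = embed_all(x[start_frame: first + period])
    vectors = vectors[:period]
    if len(vectors) < period:
        raise InitializationError("not enough embeddings for one period")
    return ReferenceCycle(vectors, segment_map(period), period, first)


def assign_phase(v: np.ndarray, ref: ReferenceCycle) -> int:
    """Phase segment of the reference vector nearest (Euclidean) to ``v``;
    ties broken toward the lowest reference index."""
    d = ref.vectors - np.asarray(v)[None, :]
    j = int(np.argmin(np.einsum("ij,ij->i", d, d)))
    return int(ref.segment_of[j])


def assign_phases(vectors: np.ndarray, ref: ReferenceCycle) -> np.ndarray:
    """Vectorized :func:`assign_phase` for a stack of embedding vectors."""
    if len(vectors) == 0:
        return np.empty(0, dtype=int)
    # direct differences (not the expanded quadratic form) so distances are
    # bitwise identical to the scalar path and ties break identically
    d = vectors[:, None, :] - ref.vectors[None, :, :]
    d2 = np.einsum("ipj,ipj->ip", d, d)
    return ref.segment_of[np.argmin(d2, axis=1)]
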