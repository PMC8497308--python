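"""End-to-end detection pipeline: video in, detection score series out.

Streams the frame sequence through cardiac-phase estimation and the
per-phase background model, honoring the validity mask: disturbed or frozen
frames produce no detections and no statistics updates, and every
reinitialization trigger discards the reference cycle and all pixel
statistics, restarting initialization from scratch.  Because the detector
restarts cleanly, post-reinitialization output is independent of anything
seen before the trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phase as ph
from .background import PhaseStatistics, classify_air, sigma_floor
from .config import DetectorConfig
from .evaluate import frame_labels, k_sweep_table, roc
from .io import (AnnotationTrack, FrameSequence, RegionOfInterest,
                 ValidityMask, build_validity_mask, detect_frozen_frames)
from .postprocess import DetectionSeries, build_score


@dataclass
class DetectorOutput:
    """Per-frame raw detector state for one or more sensitivity values k."""

    fps: float
    phase: np.ndarray                 # segment index, -1 where undefined
    warm: np.ndarray                  # statistics warm and frame scored
    valid: np.ndarray                 # validity-mask view
    counts: dict[float, np.ndarray]   # k -> per-frame air-pixel counts
    reinit_frames: tuple[int, ...]

    def to_frame(self, k: float | None = None) -> pd.DataFrame:
        """Per-frame record as a DataFrame (`frame,phase,warm,air_pixel_count`)."""
        if k is None:
            k = next(iter(self.counts))
        return pd.DataFrame({
            "frame": np.arange(len(self.phase)),
            "phase": self.phase,
            "warm": self.warm,
            "air_pixel_count": self.counts[k].astype(int),
        })


def compute_validity(seq: FrameSequence, track: AnnotationTrack | None,
                     config: DetectorConfig | None = None) -> ValidityMask:
    """Frozen-frame detection combined with annotated disturbance periods."""
    config = config or DetectorConfig()
    frozen = detect_frozen_frames(seq, config.ncc_threshold)
    if track is None:
        return frozen
    return build_validity_mask(track, frozen)


def run_detector(seq: FrameSequence, validity: ValidityMask | None = None,
                 config: DetectorConfig | None = None,
                 ks: tuple[float, ...] | None = None) -> DetectorOutput:
    """Run phase estimation + background model over the whole sequence.

    ``ks`` allows several sensitivity parameters to be evaluated in one pass
    (the phase chain and the pixel statistics are k-independent; only the
    final inequality differs), which makes the k-sweep cheap.
    """
    config = config or DetectorConfig()
    if validity is None:
        validity = detect_frozen_frames(seq, config.ncc_threshold)
    if len(validity) != len(seq):
        raise ValueError("validity mask does not match the sequence length")
    if ks is None:
        ks = (config.model_k,)

    roi = config.roi or RegionOfInterest.centered(seq.width, seq.height)
    sig = ph.mean_intensity_signal(seq, roi).values

    if config.stats_roi is not None:
        stat_frames = seq.crop(config.stats_roi).frames
    else:
        stat_frames = seq.frames
    shape = stat_frames.shape[1:]

    n = len(seq)
    phase_of = np.full(n, -1, dtype=int)
    warm = np.zeros(n, dtype=bool)
    counts = {k: np.zeros(n, dtype=np.int64) for k in ks}

    stats = PhaseStatistics(shape, config.n_segments, config.model_window,
                            config.warmup_min_samples)
    win_frames = max(
        int(round(config.init_window_s * seq.fps)),
        ph.WARMUP + 2 * int(round(config.period_band_s[1] * seq.fps)) + 1,
    )

    bounds = [0, *[r for r in validity.reinit_frames if 0 < r < n], n]
    for lo, hi in zip(bounds, bounds[1:]):
        stats.reset()
        # filter state restarts at the segment boundary so nothing before the
        # reinitialization leaks into the new reference cycle or statistics
        xseg = ph.highpass_filter(
            ph.IntensitySignal(sig[lo:hi], seq.fps),
            config.filter_critical_hz, config.filter_order,
            config.filter_zero_phase,
        ).x

        ref = None
        start_rel = 0
        while start_rel + win_frames <= hi - lo:
            try:
                ref = ph.extract_reference_cycle(
                    xseg, start_rel, fps=seq.fps,
                    window_s=config.init_window_s,
                    period_band_s=config.period_band_s,
                )
                break
            except ph.InitializationError:
                start_rel += win_frames
        if ref is None:
            continue

        emb = ph.embed_all(xseg)  # row i is the embedding at segment frame i+12
        first = ref.start_frame
        seg_phases = ph.assign_phases(emb[first - ph.WARMUP:], ref)
        phase_of[lo + first: hi] = seg_phases[: hi - lo - first]

        for rel in range(first, hi - lo):
            fi = lo + rel
            if not validity.valid[fi]:
                continue
            p = phase_of[fi]
            frame = stat_frames[fi]
            if stats.is_warm(p):
                mu = stats.mean(p)
                sf = _floored_sigma(stats, p, config)
                warm[fi] = True
                diff = frame.astype(np.float64) - mu
                for k in ks:
                    counts[k][fi] = int((diff > k * sf).sum())
            stats.update(frame, p)

    return DetectorOutput(seq.fps, phase_of, warm, validity.valid.copy(),
                          counts, validity.reinit_frames)


def _floored_sigma(stats: PhaseStatistics, p: int,
                   config: DetectorConfig) -> np.ndarray:
    """Sigma image of phase p floored at the configured quantile.

    By default the quantile pools sigma values within the current phase;
    optionally across all phases with samples.
    """
    from .background import nearest_rank_quantile
    sigma = stats.std(p)
    if config.pool_sigma_across_phases:
        pool = np.concatenate([stats.std(q).ravel()
                               for q in range(stats.n_phases)
                               if stats.sample_count(q) > 0])
        q = nearest_rank_quantile(pool, config.sigma_quantile)
        return np.maximum(sigma, q)
    q = nearest_rank_quantile(sigma, config.sigma_quantile)
    return np.maximum(sigma, q)


def score_output(out: DetectorOutput, validity: ValidityMask,
                 config: DetectorConfig | None = None,
                 k: float | None = None) -> DetectionSeries:
    """Smooth and floor-correct one k's raw counts into the final score."""
    config = config or DetectorConfig()
    if k is None:
        k = next(iter(out.counts))
    return build_score(out.counts[k], validity, out.warm, out.fps,
                       config.median_window, config.floor_window,
                       config.floor_quantile, config.alignment,
                       config.floor_source)


def detect(seq: FrameSequence, track: AnnotationTrack | None = None,
           config: DetectorConfig | None = None) -> DetectionSeries:
    """Full pipeline at the default sensitivity: video (+ annotations for
    disturbance exclusion) to the final detection-score series."""
    config = config or DetectorConfig()
    validity = compute_validity(seq, track, config)
    out = run_detector(seq, validity, config)
    return score_output(out, validity, config)


def k_sweep(seq: FrameSequence, track: AnnotationTrack,
            k_values: tuple[float, ...] = (2.0, 3.0, 4.0),
            config: DetectorConfig | None = None,
            min_grade: int = 1) -> pd.DataFrame:
    """Frame-level AUC for each sensitivity parameter k (single pass)."""
    config = config or DetectorConfig()
    validity = compute_validity(seq, track, config)
    out = run_detector(seq, validity, config, ks=tuple(k_values))
    labels, excluded = frame_labels(track, min_grade)
    aucs = {}
    for k in k_values:
        series = score_output(out, validity, config, k)
        aucs[k] = roc(series, labels, excluded).auc
    return k_sweep_table(aucs)
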