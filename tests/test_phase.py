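"""Cardiac signal, Butterworth filtering, delay embedding, phase matching."""

import numpy as np
import pytest
from scipy import signal as sps

from teevae.io import FrameSequence, RegionOfInterest
from teevae.phase import (EMBED_DELAY, EMBED_DIM, N_SEGMENTS, WARMUP,
                          InitializationError, IntensitySignal, assign_phase,
                          assign_phases, butter_highpass, embed, embed_all,
                          estimate_period, extract_reference_cycle,
                          highpass_filter, mean_intensity_signal, segment_map)


class TestMeanIntensity:
    def test_constant_frames(self):
        seq = FrameSequence(np.full((5, 20, 30), 100, np.uint8), 38.0)
        sig = mean_intensity_signal(seq, RegionOfInterest(0, 0, 30, 20))
        assert np.allclose(sig.values, 100.0)

    def test_half_and_half(self):
        frame = np.zeros((20, 30), np.uint8)
        frame[:10] = 200
        seq = FrameSequence(frame[None], 38.0)
        sig = mean_intensity_signal(seq, RegionOfInterest(0, 0, 30, 20))
        assert sig.values[0] == pytest.approx(100.0)

    def test_matches_two_loop_summation(self, rng):
        frame = rng.integers(0, 255, (16, 18), dtype=np.uint8)
        seq = FrameSequence(frame[None], 38.0)
        roi = RegionOfInterest(3, 2, 10, 11)
        got = mean_intensity_signal(seq, roi).values[0]
        total = 0.0
        for y in range(2, 13):
            for x in range(3, 13):
                total += float(frame[y, x])
        assert got == pytest.approx(total / 110.0, abs=1e-9)

    def test_roi_outside_frame(self):
        seq = FrameSequence(np.zeros((1, 10, 10), np.uint8), 38.0)
        with pytest.raises(ValueError):
            mean_intensity_signal(seq, RegionOfInterest(5, 5, 10, 10))


class TestHighpassFilter:
    def test_dc_rejection(self):
        sig = IntensitySignal(np.full(400, 87.0), 38.0)
        out = highpass_filter(sig).x
        assert np.max(np.abs(out)) < 1e-6

    @pytest.mark.parametrize("freq", [8.0, 12.0, 15.0])
    def test_steady_state_sinusoid_gain(self, freq):
        """Output amplitude equals |H(e^{jw})| of the designed digital filter."""
        fs = 38.0
        n = np.arange(3000)
        sig = IntensitySignal(100.0 + np.sin(2 * np.pi * freq * n / fs), fs)
        out = highpass_filter(sig).x[1500:]
        t = n[1500:] / fs
        # amplitude via projection onto quadrature pair
        c = 2 * np.mean(out * np.cos(2 * np.pi * freq * t))
        s = 2 * np.mean(out * np.sin(2 * np.pi * freq * t))
        amp = np.hypot(c, s)
        b, a = butter_highpass(fs)
        _, h = sps.freqz(b, a, worN=[2 * np.pi * freq / fs])
        assert amp == pytest.approx(abs(h[0]), abs=1e-3)

    def test_minus_3db_at_critical_frequency(self):
        b, a = butter_highpass(38.0, critical_hz=5.0)
        _, h = sps.freqz(b, a, worN=[2 * np.pi * 5.0 / 38.0])
        assert abs(h[0]) == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_matches_direct_recursion(self, rng):
        """A delayed impulse comes out as the filter's impulse response,
        computed independently by running the difference equation."""
        fs = 38.0
        x = np.zeros(80)
        x[5] = 1.0
        out = highpass_filter(IntensitySignal(x, fs)).x
        b, a = butter_highpass(fs)
        y = np.zeros_like(x)
        for n in range(len(x)):
            acc = 0.0
            for i in range(len(b)):
                if n - i >= 0:
                    acc += b[i] * x[n - i]
            for j in range(1, len(a)):
                if n - j >= 0:
                    acc -= a[j] * y[n - j]
            y[n] = acc / a[0]
        assert np.allclose(out, y, atol=1e-12)

    def test_critical_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass_filter(IntensitySignal(np.zeros(10), 8.0), critical_hz=5.0)

    def test_zero_phase_option(self):
        sig = IntensitySignal(np.sin(np.arange(500)), 38.0)
        out = highpass_filter(sig, zero_phase=True).x
        assert len(out) == 500


class TestEmbedding:
    def test_ramp(self):
        x = np.arange(20, dtype=float)
        assert np.array_equal(embed(x, 12), [0, 3, 6, 9, 12])

    def test_constant(self):
        assert np.array_equal(embed(np.full(20, 7.0), 15), [7] * 5)

    def test_sine_components(self):
        x = np.sin(2 * np.pi * np.arange(60) / 20)
        v = embed(x, 40)
        expected = [np.sin(2 * np.pi * m / 20) for m in (28, 31, 34, 37, 40)]
        assert np.allclose(v, expected)

    def test_warmup_boundary(self):
        with pytest.raises(ValueError):
            embed(np.arange(20.0), 11)

    def test_embed_all_agrees_with_scalar(self, rng):
        x = rng.normal(size=50)
        mat = embed_all(x)
        assert mat.shape == (50 - WARMUP, EMBED_DIM)
        for i in range(len(mat)):
            assert np.array_equal(mat[i], embed(x, i + WARMUP))


class TestReferenceCycle:
    def test_sinusoid_period_30(self):
        fs = 38.0
        x = np.sin(2 * np.pi * np.arange(400) / 30)
        ref = extract_reference_cycle(x, 0, fps=fs)
        assert ref.period_frames == 30
        sizes = np.bincount(ref.segment_of, minlength=N_SEGMENTS)
        assert np.all(sizes == 2)

    def test_period_31_segment_sizes(self):
        sizes = np.bincount(segment_map(31), minlength=N_SEGMENTS)
        assert sizes.sum() == 31
        assert set(sizes) <= {2, 3}
        assert sizes.max() - sizes.min() <= 1

    def test_segment_lengths_never_differ_by_more_than_one(self):
        for period in range(16, 77):
            sizes = np.bincount(segment_map(period), minlength=N_SEGMENTS)
            assert sizes.min() >= 1
            assert sizes.max() - sizes.min() <= 1

    def test_constant_signal_fails(self):
        with pytest.raises(InitializationError):
            extract_reference_cycle(np.zeros(500), 0, fps=38.0)

    def test_autocorrelation_oracle(self, rng):
        """Estimated period equals a brute-force autocorrelation argmax."""
        fs = 38.0
        n = np.arange(300)
        x = np.sin(2 * np.pi * n / 26) + 0.05 * rng.normal(size=300)
        got = estimate_period(x, fs)
        xc = x - x.mean()
        lags = range(int(0.4 * fs), int(2.0 * fs) + 1)
        brute = max(lags, key=lambda L: float(np.dot(xc[:-L], xc[L:])))
        assert got == brute == 26


class TestAssignPhase:
    def _ref(self):
        x = np.sin(2 * np.pi * np.arange(400) / 30)
        return extract_reference_cycle(x, 0, fps=38.0)

    def test_exact_reference_vector(self):
        ref = self._ref()
        for j in (0, 7, 29):
            assert assign_phase(ref.vectors[j], ref) == ref.segment_of[j]

    def test_tie_breaks_to_lower_index(self):
        from teevae.phase import ReferenceCycle
        vectors = np.array([[0.0, 0, 0, 0, 1], [0.0, 0, 0, 0, -1]])
        ref = ReferenceCycle(vectors, np.array([3, 9]), 2, 0)
        # query equidistant to both reference vectors
        assert assign_phase(np.zeros(5), ref) == 3

    def test_agrees_with_brute_force_scan(self, rng):
        ref = self._ref()
        for _ in range(100):
            v = rng.normal(size=5)
            dists = [np.linalg.norm(v - r) for r in ref.vectors]
            j = int(np.argmin(dists))
            assert assign_phase(v, ref) == ref.segment_of[j]
        queries = rng.normal(size=(50, 5))
        brute = [ref.segment_of[int(np.argmin([np.linalg.norm(q - r)
                                               for r in ref.vectors]))]
                 for q in queries]
        assert np.array_equal(assign_phases(queries, ref), brute)

    def test_noiseless_periodic_signal_cycles_through_segments(self):
        x = np.sin(2 * np.pi * np.arange(1000) / 30)
        ref = extract_reference_cycle(x, 0, fps=38.0)
        phases = assign_phases(embed_all(x)[ref.start_frame - WARMUP:], ref)
        # periodic with the cycle period
        assert np.array_equal(phases[:-30], phases[30:])
        # visits all 15 segments in cyclic (non-decreasing mod 15) order
        one_cycle = phases[:30]
        assert set(one_cycle) == set(range(N_SEGMENTS))
        diffs = np.diff(np.r_[one_cycle, one_cycle[0] + N_SEGMENTS])
        assert np.all((diffs >= 0) & (diffs <= 2))


class TestPhaseConsistency:
    def test_matches_generator_ground_truth(self, quiet_scene):
        """>=90% of frames within +/-1 segment of the true cardiac phase
        (up to the arbitrary anchoring offset of the reference cycle)."""
        from teevae.config import DetectorConfig
        from teevae.pipeline import compute_validity, run_detector
        out = run_detector(quiet_scene.video,
                           compute_validity(quiet_scene.video,
                                            quiet_scene.annotations))
        defined = out.phase >= 0
        assert defined.sum() > 1000
        true_seg = np.floor(quiet_scene.true_phase * N_SEGMENTS).astype(int)
        best = 0.0
        for offset in range(N_SEGMENTS):
            d = np.abs((out.phase[defined] - true_seg[defined] - offset)
                       % N_SEGMENTS)
            d = np.minimum(d, N_SEGMENTS - d)
            best = max(best, float(np.mean(d <= 1)))
        assert best >= 0.90
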