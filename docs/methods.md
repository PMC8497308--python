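# Methods

## Detection model

The detector assumes the TEE video is quasi-periodic: conditioned on the
cardiac phase, each pixel's intensity is approximately stationary and
Gaussian, and air bubbles are bright outliers against that background.
Three stages implement this.

**Cardiac phase.** The spatial mean intensity over a rectangular region
(367 × 377 px by default, clipped to the frame and centered — the region's
placement is not critical because only its mean enters the signal) is
high-pass filtered with a causal 2nd-order digital Butterworth filter at a
critical frequency of 5 Hz. The filter is realized by bilinear transform
(`scipy.signal.butter`) and its state is initialized to the steady-state
response of the first sample's level, so a segment that begins at an
arbitrary brightness produces no startup transient; DC gain is exactly zero
and the magnitude at the critical frequency is −3 dB. A zero-phase
(forward–backward) variant exists for offline use. Note that 5 Hz lies
*above* the cardiac fundamental (~1–2 Hz): at ~38 fps the filter passes
only upper harmonics of the heartbeat plus fast transients. This
configuration is kept as the default deliberately; cutoff, order and pass
direction are exposed for users who prefer a fundamental-preserving band.

The filtered sequence is delay-embedded into 5-vectors with a 3-frame lag
(a Takens-style state reconstruction). During initialization the cardiac
period is estimated as the autocorrelation-maximizing lag within a
physiologic band of 0.4–2.0 s (30–150 bpm) over a 5-s window — long enough
for at least two cycles at the slow end. A flat or near-flat signal raises
an initialization error and the pipeline retries one window later. One
period of embedding vectors forms the reference cycle, partitioned into 15
contiguous phase segments of as-equal-as-possible length
(segment(i) = ⌊15·i/period⌋, so segment sizes differ by at most one).
Subsequent frames take the segment of the Euclidean-nearest reference
vector, ties broken toward the lower reference index. Frames before the
reference cycle is available have undefined phase and produce no
detections.

**Background model.** For each of the 15 phases and every pixel, a ring
buffer keeps the last 30 same-phase frames (a hard window, not exponential
forgetting); rolling mean μ and *population* standard deviation σ (divide
by count) are maintained exactly via integer sums. σ is floored at the 65%
quantile — nearest rank, i.e. the ⌈0.65·N⌉-th order statistic — of the
current phase's σ image, recomputed at every classification; a
configuration flag pools the quantile across phases instead. A pixel is
air iff I − μ > k·σ_floored, strictly, one-sided (darkening can never be
air); k defaults to 3. A phase produces detections only once its buffer
holds ≥ 15 samples (half the window) — earlier σ estimates are too
unstable — and frames classified before that report a count of zero and
are flagged not-warm. Classification precedes the buffer update, so a
frame is never compared against statistics containing itself.

**Score.** Raw per-frame air-pixel counts are smoothed with a rolling
median of window 140 frames — trailing/causal (lower-median on even
windows, which keeps integer counts integer); a centered option exists for
offline replication. Per reinitialization-delimited segment, the noise
floor (nearest-rank 15% quantile of the first 140 usable frames of the
smoothed series; a flag switches the source to the raw counts) is
subtracted and the result clipped at zero. Frames excluded by the validity
mask, or not-warm, are *skipped* — not zero-filled — in both the median
window and the floor window, since zero-filling would bias the floor
downward; the floor window likewise counts only valid, warm frames, because
warm-up frames report zero by contract and would otherwise drag the floor
to zero.

**Exclusions and reinitialization.** A frame whose zero-normalized
cross-correlation with its predecessor reaches 0.999 is a frozen-transfer
frame (for zero-variance frames the NCC is defined as 1 for bitwise
identity, else 0 — flat identical frames are exactly the freeze
signature). Frozen frames and annotated overlay / probe-repositioning /
freeze periods are excluded from analysis; the end of every frozen run,
freeze interval and probe-repositioning interval triggers a full
reinitialization: reference cycle and all pixel statistics are discarded
and rebuilt from scratch, and the high-pass filter state restarts at the
boundary, so post-reinitialization output is provably independent of
anything before the trigger.

## Evaluation protocol

Frame-level ROC compares the score against the graded visible-air
reference on valid frames. With `min_grade=2`, grade-1 frames are removed
from the analysis entirely (neither positive nor negative); ungraded
sporadic-bubble frames are plain negatives. AUC is the trapezoidal area
over the distinct-threshold sweep, which equals the Mann–Whitney
concordance statistic with ties counted one half (asserted against an
O(n²) oracle and scikit-learn in the tests).

For alarming, supra-threshold frames at most 38 frames (~1 s) apart merge
into one alarm event. An annotated event counts as detected at threshold t
if any valid frame within 3 s of its start scores above t (frames after
the window still contribute to the ROC, just not to detection timing). The
operating threshold is the largest candidate score value at which the
detected fraction reaches the target (0.9 by default); candidates include
0, and since scores are non-negative an identically-zero score makes the
target unreachable, which is reported with a flag rather than by silently
dropping the threshold below zero. A merged alarm overlapping *any*
visible-air interval by at least one frame is not false — this includes
grade-1 intervals when `min_grade=2`, whose frames are excluded rather
than negative. The false-alarm rate divides by minutes of valid analyzed
video. Reported percentages round to the nearest integer, ties away from
zero.

## Synthetic scene generator

The generator emulates exactly the statistical structure the detector
assumes, with residual noise — not ultrasound physics. A static
low-frequency tissue template (brightness 60–140 by default) is modulated
by a dark chamber (level 10) whose radius oscillates sinusoidally with the
cardiac period (0.8 s, i.e. 75 bpm, with ±3% per-cycle jitter so the phase
matcher is exercised off the metronomic case). The template is multiplied
by Rayleigh speckle (scale 0.8, putting the speckle mean near 1): two
Gaussian component stacks over 24 phase bins are smoothed circularly along
the phase axis (correlation length 0.5 cycles) and combined as
√(g₁²+g₂²), so every (pixel, phase) sample is *exactly* Rayleigh while
nearby phases stay strongly correlated and opposite phases decorrelate
substantially. This makes phase conditioning genuinely necessary (an
unconditioned background model would see large variance) while keeping the
within-segment residual small. Additive Gaussian jitter (σ = 2 intensity
units) is the irreducible noise. An earlier construction with independent
speckle per phase bin was discarded: a 15-segment detector phase straddles
independent bins, which inflates the within-phase σ to the order of the
tissue brightness and breaks the very stationarity the generator is
supposed to realize.

Bubbles arrive as a Poisson stream during each graded event (defaults 5 /
20 / 60 bubbles·s⁻¹ for grades 1/2/3 — continuous flow, not isolated
bubbles), enter near the top of the chamber, advect downward at
3 px/frame, and die on reaching the wall. Each adds a fixed hyperechoic
increment (default 80, clipped at 255) over a disk of radius 3 px,
rendered only inside the chamber; the rendered disks are retained per
frame as pixel-level ground truth. Artifacts: `freeze` repeats the last
pre-freeze frame bitwise, `overlay` draws an opaque rectangle,
`probe_shift` translates the anatomy permanently. Identical parameters and
seed give byte-identical output.

What the generator does **not** model: beamforming and point-spread
effects, anatomically correct chambers, valve/papillary structures,
respiratory motion, dysrhythmia beyond period jitter, probe-rotation view
changes. Consequently, passing tests show the algorithm is implemented
correctly and behaves as designed in its assumed regime; they do not
predict clinical sensitivity or false-alarm rates, where moving valvular
structures are the dominant false-positive source.

## Benchmark problem sizes

The reference benchmark (`teevae.benchmark`) is a seeded 10-minute scene
at 38 fps with nine 20-s events (3 × each grade), one overlay and one
freeze, plus a 4-minute scene with five strong grade-3 events for the
operating-point check. Frames are 280 × 200 px: a deliberate reduction
from the recorded 628 × 458 geometry (which remains the generator default)
so a complete benchmark run — generation, detection with three k values,
evaluation — fits in well under two minutes and a couple of GiB on a
single CPU. Bubble rates for the benchmark are 4 / 10 / 25 s⁻¹, keeping
grade-3 air-pixel occupancy per same-phase pixel below ~10%; above that, a
rolling background model progressively absorbs the bubbles themselves
(μ rises, σ inflates) and sensitivity collapses late in long events — an
intrinsic property of background subtraction worth knowing about, not a
bug.

## Numerical choices and edge cases

- Intensities are uint8 throughout; windowed statistics use exact integer
  sums, so μ/σ equal a direct recompute of the buffer to float rounding.
- Nearest-rank quantiles and lower medians are order statistics: fully
  deterministic, interpolation-free, integer-preserving.
- Phase-assignment distances are computed from explicit differences (not
  the expanded quadratic form) so vectorized and scalar paths break ties
  identically.
- Variable-frame-rate input is not resampled internally; all windows are
  defined in frames at the nominal fps supplied with the sequence.
- The background model runs on the full frame by default; the ROI feeds
  only the cardiac signal. Both regions are configurable.
- Grade intervals must not overlap each other; disturbance intervals may
  overlap anything. Annotation CSVs use 0-based, half-open intervals.

## Known limitations

- The 5 Hz high-pass default follows the published configuration even
  though it suppresses the cardiac fundamental at typical frame rates; on
  data with weak harmonics the phase estimate may degrade. The cutoff is
  configurable.
- Long continuous high-grade events saturate the rolling background (see
  above); the 30-frame window then partially adapts to the air itself.
- Alarm/operating-point statistics assume annotated event starts are
  accurate to a few frames; heavily delayed annotations would distort the
  3-s response-window bookkeeping.
- The synthetic benchmark's AUC figures characterize the implementation
  under the generator's assumptions, not clinical performance.
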