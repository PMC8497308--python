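"""Synthetic TEE-like video with ground-truth graded bubble streams.

The generator emulates the statistical structure the detector assumes: a
quasi-periodic speckled cardiac scene.  A static tissue template is modulated
by a dark chamber whose radius oscillates with the cardiac period, multiplied
by Rayleigh speckle drawn once per (pixel, phase bin) and reused every cycle
with small additive Gaussian jitter — so the phase-conditioned per-pixel
Gaussian background model is approximately correct, with residual noise.
Air bubbles are rendered as bright disks advected through the chamber, a
fixed hyperechoic increment above the local background; their rendered masks
are retained as pixel-level ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import AnnotationTrack, FrameSequence


@dataclass
class SceneParams:
    """Scene geometry, timing and noise parameters.

    Defaults mirror the recording conditions of the study data: 628 x 458 px
    at 38 fps, cardiac period 0.8 s (75 bpm).  ``speckle_scale`` is the
    Rayleigh scale of the multiplicative speckle (0.8 puts the speckle mean
    near 1 so the template sets the local brightness); ``jitter_sigma`` is the
    additive per-frame Gaussian noise in intensity units; ``period_jitter``
    is the relative per-cycle heart-period jitter (+/-3% by default, so phase
    assignment is exercised off the metronomic case).
    """

    fps: float = 38.0
    duration_s: float = 10.0
    period_s: float = 0.8
    width: int = 628
    height: int = 458
    speckle_scale: float = 0.8
    jitter_sigma: float = 2.0
    period_jitter: float = 0.03
    n_speckle_bins: int = 24
    speckle_smooth_cycles: float = 0.5
    chamber_center: tuple[float, float] | None = None   # (x, y); default frame center
    chamber_radius_frac: tuple[float, float] = (0.175, 0.24)  # of min(width, height)
    tissue_level: tuple[float, float] = (60.0, 140.0)
    chamber_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_s <= 2.0 / self.fps:
            raise ValueError("cardiac period must exceed two frame intervals")
        if self.width <= 0 or self.height <= 0 or self.duration_s <= 0:
            raise ValueError("dimensions and duration must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def center(self) -> tuple[float, float]:
        if self.chamber_center is not None:
            return self.chamber_center
        return (self.width / 2.0, self.height / 2.0)

    @property
    def radius_range(self) -> tuple[float, float]:
        m = min(self.width, self.height)
        return (self.chamber_radius_frac[0] * m, self.chamber_radius_frac[1] * m)


@dataclass
class BubbleEvent:
    """A period of continuous air-bubble flow of a given optical grade.

    ``bubble_rate`` (bubbles entering per second) increases with grade; grade
    defaults follow the minor / medium / major convention.  Bubbles appear
    hyperechoic: each adds ``bubble_intensity`` (clipped to 255) over a disk
    of ``bubble_radius_px``.
    """

    start_frame: int
    end_frame: int
    grade: int
    bubble_rate: float | None = None
    bubble_intensity: float = 80.0
    bubble_radius_px: float = 3.0
    velocity_px_per_frame: float = 3.0

    #: default continuous-flow rates per grade (bubbles/s)
    DEFAULT_RATES = {1: 5.0, 2: 20.0, 3: 60.0}

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3):
            raise ValueError("grade must be 1, 2 or 3")
        if self.start_frame >= self.end_frame:
            raise ValueError("empty bubble event")
        if self.bubble_rate is None:
            self.bubble_rate = self.DEFAULT_RATES[self.grade]

    @property
    def label(self) -> str:
        return f"grade{self.grade}"


@dataclass
class ArtifactEvent:
    """A video disturbance: transfer freeze, overlay box, or probe shift.

    ``freeze`` repeats the last pre-freeze frame bitwise; ``overlay`` draws an
    opaque rectangle; ``probe_shift`` translates the anatomy permanently by
    ``shift_px`` (x, y) from ``start_frame`` on.
    """

    kind: str
    start_frame: int
    end_frame: int
    shift_px: tuple[int, int] = (0, 0)

    LABELS = {"freeze": "freeze", "overlay": "overlay", "probe_shift": "probe_reposition"}

    def __post_init__(self) -> None:
        if self.kind not in self.LABELS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.start_frame >= self.end_frame:
            raise ValueError("empty artifact event")

    @property
    def label(self) -> str:
        return self.LABELS[self.kind]


@dataclass
class SyntheticScene:
    """Bundle of generated video, annotations and ground truth."""

    video: FrameSequence
    annotations: AnnotationTrack
    #: instantaneous cardiac phase in [0, 1) per frame
    true_phase: np.ndarray
    #: per-frame list of rendered bubble disks (x, y, radius)
    bubbles: list[list[tuple[float, float, float]]]
    params: SceneParams

    def bubble_mask(self, n: int) -> np.ndarray:
        """Boolean mask of pixels covered by a rendered bubble in frame ``n``."""
        mask = np.zeros((self.params.height, self.params.width), dtype=bool)
        for x, y, r in self.bubbles[n]:
            _disk(mask, x, y, r)
        return mask


class MaskSequence:
    """Lazy per-frame ground-truth bubble masks (rasterized on access)."""

    def __init__(self, scene: SyntheticScene):
        self._scene = scene

    def __len__(self) -> int:
        return len(self._scene.video)

    def __getitem__(self, n: int) -> np.ndarray:
        return self._scene.bubble_mask(n)

    def __iter__(self):
        for n in range(len(self)):
            yield self[n]


def ground_truth_masks(scene: SyntheticScene) -> MaskSequence:
    """Per-frame binary masks of rendered bubble pixels."""
    return MaskSequence(scene)


def _disk(mask: np.ndarray, x: float, y: float, r: float) -> None:
    """Set mask pixels whose centers lie within radius r of (x, y)."""
    h, w = mask.shape
    x0, x1 = max(0, int(math.floor(x - r))), min(w - 1, int(math.ceil(x + r)))
    y0, y1 = max(0, int(math.floor(y - r))), min(h - 1, int(math.ceil(y + r)))
    if x0 > x1 or y0 > y1:
        return
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    mask[y0:y1 + 1, x0:x1 + 1] |= (xx - x) ** 2 + (yy - y) ** 2 <= r * r


def _tissue_template(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency brightness field standing in for tissue anatomy."""
    lo, hi = params.tissue_level
    coarse = rng.uniform(0.0, 1.0, size=(10, 12))
    zoom = (params.height / coarse.shape[0], params.width / coarse.shape[1])
    smooth = ndimage.zoom(coarse, zoom, order=3, mode="nearest")
    smooth = smooth[: params.height, : params.width]
    smooth -= smooth.min()
    rng_span = smooth.max() or 1.0
    return (lo + (hi - lo) * smooth / rng_span).astype(np.float32)


def _phase_speckle(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Rayleigh speckle, one field per cardiac phase bin.

    The fields evolve smoothly around the cycle: two Gaussian component
    stacks are smoothed circularly along the phase axis (correlation length
    ``speckle_smooth_cycles`` cycles) and combined as sqrt(g1^2 + g2^2), so
    every (pixel, bin) sample is exactly Rayleigh(``speckle_scale``) while
    nearby phases stay strongly correlated — the phase-conditioned
    stationarity a per-phase background model assumes — and phases half a
    cycle apart decorrelate substantially.
    """
    nb, h, w = params.n_speckle_bins, params.height, params.width
    sigma_bins = params.speckle_smooth_cycles * nb
    g = rng.standard_normal((2, nb, h, w))
    if sigma_bins > 0:
        g = ndimage.gaussian_filter1d(g, sigma=sigma_bins, axis=1, mode="wrap")
        # restore unit variance: smoothing scales it by the sum of squared
        # (wrapped) kernel weights, identical for every pixel and bin
        impulse = np.zeros(nb)
        impulse[0] = 1.0
        kernel = ndimage.gaussian_filter1d(impulse, sigma=sigma_bins, mode="wrap")
        g /= np.sqrt(np.sum(kernel ** 2))
    return (params.speckle_scale
            * np.sqrt(g[0] ** 2 + g[1] ** 2)).astype(np.float32)


def _check_events(params: SceneParams, bubbles: list[BubbleEvent],
                  artifacts: list[ArtifactEvent]) -> None:
    n = params.n_frames
    for ev in list(bubbles) + list(artifacts):
        if ev.start_frame < 0 or ev.end_frame > n:
            raise ValueError(f"event ({ev.start_frame},{ev.end_frame}) outside video of {n} frames")
    iv = sorted((b.start_frame, b.end_frame, b.grade) for b in bubbles)
    for (s1, e1, g1), (s2, e2, g2) in zip(iv, iv[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping bubble events at frames {s2} < {e1}")


def generate_scene(params: SceneParams,
                   bubbles: list[BubbleEvent] | None = None,
                   artifacts: list[ArtifactEvent] | None = None) -> SyntheticScene:
    """Render a quasi-periodic speckled scene with bubbles and artifacts.

    Identical parameters, events and seed reproduce byte-identical output.
    Returns a :class:`SyntheticScene` whose annotation track labels every
    bubble event with its optical grade and every artifact with its kind.
    """
    bubbles = list(bubbles or [])
    artifacts = list(artifacts or [])
    _check_events(params, bubbles, artifacts)

    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    n_frames = params.n_frames
    template = _tissue_template(params, rng)

    speckle = _phase_speckle(params, rng)

    cx, cy = params.center
    rmin, rmax = params.radius_range
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)

    # instantaneous phase with per-cycle period jitter
    true_phase = np.empty(n_frames)
    phase = 0.0
    period_frames = params.period_s * params.fps
    cur_period = period_frames * (1.0 + rng.uniform(-params.period_jitter,
                                                    params.period_jitter))
    for nf in range(n_frames):
        true_phase[nf] = phase
        phase += 1.0 / cur_period
        if phase >= 1.0:
            phase -= 1.0
            cur_period = period_frames * (1.0 + rng.uniform(
                -params.period_jitter, params.period_jitter))

    # per-frame bubble spawning (Poisson arrivals during each event)
    active: list[dict] = []
    frame_bubbles: list[list[tuple[float, float, float]]] = [[] for _ in range(n_frames)]
    event_at = np.full(n_frames, -1, dtype=int)
    for i, ev in enumerate(bubbles):
        event_at[ev.start_frame:ev.end_frame] = i

    shift_events = sorted((a for a in artifacts if a.kind == "probe_shift"),
                          key=lambda a: a.start_frame)
    overlay_events = [a for a in artifacts if a.kind == "overlay"]
    freeze_events = sorted((a for a in artifacts if a.kind == "freeze"),
                           key=lambda a: a.start_frame)

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    shift_x = shift_y = 0

    for nf in range(n_frames):
        for a in shift_events:
            if a.start_frame == nf:
                shift_x += a.shift_px[0]
                shift_y += a.shift_px[1]
        ph = true_phase[nf]
        b = min(int(ph * params.n_speckle_bins), params.n_speckle_bins - 1)
        radius = rmin + (rmax - rmin) * (0.5 + 0.5 * math.sin(2 * math.pi * ph))
        ccx, ccy = cx + shift_x, cy + shift_y
        chamber = (xx - ccx) ** 2 + (yy - ccy) ** 2 <= radius * radius

        base = template.copy()
        if shift_x or shift_y:
            base = np.roll(base, (shift_y, shift_x), axis=(0, 1))
        base[chamber] = params.chamber_level
        img = base * speckle[b]

        # spawn and advect bubbles
        ei = event_at[nf]
        if ei >= 0:
            ev = bubbles[ei]
            for _ in range(rng.poisson(ev.bubble_rate / params.fps)):
                ang = rng.uniform(0, 2 * math.pi)
                # enter near the top of the chamber, drift downward
                bx = ccx + 0.6 * radius * math.cos(ang)
                by = ccy - 0.8 * radius + rng.uniform(-0.1, 0.1) * radius
                active.append({"x": bx, "y": by, "r": ev.bubble_radius_px,
                               "v": ev.velocity_px_per_frame,
                               "amp": ev.bubble_intensity})
        survivors = []
        for bub in active:
            bub["y"] += bub["v"]
            inside = (bub["x"] - ccx) ** 2 + (bub["y"] - ccy) ** 2 <= (radius - bub["r"]) ** 2
            if not inside:
                continue
            survivors.append(bub)
            x0 = max(0, int(math.floor(bub["x"] - bub["r"])))
            x1 = min(w - 1, int(math.ceil(bub["x"] + bub["r"])))
            y0 = max(0, int(math.floor(bub["y"] - bub["r"])))
            y1 = min(h - 1, int(math.ceil(bub["y"] + bub["r"])))
            if x0 > x1 or y0 > y1:
                continue
            sub_y, sub_x = np.mgrid[y0:y1 + 1, x0:x1 + 1]
            disk = ((sub_x - bub["x"]) ** 2 + (sub_y - bub["y"]) ** 2
                    <= bub["r"] ** 2) & chamber[y0:y1 + 1, x0:x1 + 1]
            img[y0:y1 + 1, x0:x1 + 1][disk] += bub["amp"]
            if disk.any():
                frame_bubbles[nf].append((bub["x"], bub["y"], bub["r"]))
        active = survivors

        if params.jitter_sigma > 0:
            img += rng.normal(0.0, params.jitter_sigma, size=(h, w)).astype(np.float32)

        for a in overlay_events:
            if a.start_frame <= nf < a.end_frame:
                oy, ox = h // 6, w // 6
                img[oy:oy + h // 4, ox:ox + w // 2] = 200.0

        frames[nf] = np.clip(img, 0, 255).astype(np.uint8)

    # freezes repeat the last pre-freeze frame bitwise
    for a in freeze_events:
        src = max(a.start_frame - 1, 0)
        frames[a.start_frame:a.end_frame] = frames[src]
        for nf in range(a.start_frame, a.end_frame):
            frame_bubbles[nf] = list(frame_bubbles[src])

    intervals = [(ev.start_frame, ev.end_frame, ev.label) for ev in bubbles]
    intervals += [(a.start_frame, a.end_frame, a.label) for a in artifacts]
    track = AnnotationTrack(sorted(intervals), n_frames)
    video = FrameSequence(frames, params.fps)
    return SyntheticScene(video, track, true_phase, frame_bubbles, params)
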