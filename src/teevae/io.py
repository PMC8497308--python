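"""Frame-sequence and annotation I/O, analysis region, frozen-frame detection.

The detector consumes grayscale TEE video as an ordered stack of 8-bit frames
plus a CSV annotation track of labelled intervals (visible-air grade 1-3 and
disturbance periods).  Disturbed or frozen frames are excluded from analysis
and trigger reinitialization of the detector state.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: labels a grade interval may carry, in increasing severity
GRADE_LABELS = ("grade1", "grade2", "grade3")
#: labels of disturbance intervals excluded from analysis
DISTURBANCE_LABELS = ("overlay", "probe_reposition", "freeze")
ALL_LABELS = GRADE_LABELS + DISTURBANCE_LABELS

# ITU-R BT.601 luma weights for RGB -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


class VideoFormatError(ValueError):
    """Raised when a video file cannot be interpreted as a frame sequence."""


class AnnotationFormatError(ValueError):
    """Raised when an annotation CSV violates the interval grammar."""


@dataclass
class RegionOfInterest:
    """Rectangular analysis region, used for the cardiac mean-intensity signal.

    The study used a 367 x 377 px rectangle; its placement within the frame is
    not critical because only the spatial mean enters the cardiac signal, so
    the default is centered (see :func:`RegionOfInterest.centered`).
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI offset must be non-negative")

    @classmethod
    def centered(cls, frame_width: int, frame_height: int,
                 width: int = 367, height: int = 377) -> "RegionOfInterest":
        """Default ROI: requested size, clipped to the frame, centered."""
        w = min(width, frame_width)
        h = min(height, frame_height)
        return cls((frame_width - w) // 2, (frame_height - h) // 2, w, h)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.height),
                slice(self.x0, self.x0 + self.width))

    def validate_within(self, frame_width: int, frame_height: int) -> None:
        if self.x0 + self.width > frame_width or self.y0 + self.height > frame_height:
            raise ValueError(
                f"ROI {self.width}x{self.height}@({self.x0},{self.y0}) exceeds "
                f"frame {frame_width}x{frame_height}"
            )


@dataclass
class FrameSequence:
    """Ordered grayscale video frames with a nominal frame rate.

    ``frames`` is an (n_frames, height, width) uint8 array; all window sizes
    downstream are expressed in frames at ``fps``.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise VideoFormatError("frames must be a (n, height, width) stack")
        if len(self.frames) == 0:
            raise VideoFormatError("empty frame sequence")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frames.dtype != np.uint8:
            arr = np.asarray(self.frames, dtype=float)
            if arr.min() < 0 or arr.max() > 255:
                raise VideoFormatError("intensities must lie in [0, 255]")
            self.frames = np.rint(arr).astype(np.uint8)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def crop(self, roi: RegionOfInterest) -> "FrameSequence":
        roi.validate_within(self.width, self.height)
        ys, xs = roi.slices()
        return FrameSequence(self.frames[:, ys, xs].copy(), self.fps)


@dataclass
class AnnotationTrack:
    """Labelled half-open frame intervals ``(start, end, label)``.

    Grade intervals (visible air, grade1 < grade2 < grade3 in severity) must
    not overlap one another; disturbance intervals may overlap anything.
    """

    intervals: list[tuple[int, int, str]]
    total_frames: int

    def __post_init__(self) -> None:
        for start, end, label in self.intervals:
            if label not in ALL_LABELS:
                raise AnnotationFormatError(f"unknown label {label!r}")
            if not (0 <= start < end <= self.total_frames):
                raise AnnotationFormatError(
                    f"interval ({start}, {end}) outside [0, {self.total_frames}]"
                )
        grade_iv = sorted(
            (s, e) for s, e, lab in self.intervals if lab in GRADE_LABELS
        )
        for (s1, e1), (s2, e2) in zip(grade_iv, grade_iv[1:]):
            if s2 < e1:
                raise AnnotationFormatError(
                    f"grade intervals overlap: ({s1},{e1}) and ({s2},{e2})"
                )

    def grade_intervals(self, min_grade: int = 1) -> list[tuple[int, int, int]]:
        """Visible-air intervals of grade >= ``min_grade`` as (start, end, grade)."""
        out = []
        for s, e, lab in self.intervals:
            if lab in GRADE_LABELS:
                g = int(lab[-1])
                if g >= min_grade:
                    out.append((s, e, g))
        return sorted(out)

    def disturbance_intervals(self) -> list[tuple[int, int, str]]:
        return sorted((s, e, lab) for s, e, lab in self.intervals
                      if lab in DISTURBANCE_LABELS)


@dataclass
class ValidityMask:
    """Per-frame analysis validity plus detector reinitialization triggers.

    A frame is valid when it enters the ROC analysis; ``reinit_frames`` are the
    indices at which the reference cycle and all pixel statistics must be
    discarded (ends of frozen runs and of probe-repositioning periods).
    """

    valid: np.ndarray
    reinit_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        self.reinit_frames = tuple(sorted(set(int(r) for r in self.reinit_frames)))
        for r in self.reinit_frames:
            if not (0 <= r < len(self.valid)):
                raise ValueError(f"reinit frame {r} out of range")

    def __len__(self) -> int:
        return len(self.valid)


def _to_gray(frame: np.ndarray) -> np.ndarray:
    """Convert one decoded frame to uint8 grayscale (BT.601 luma for color)."""
    arr = np.asarray(frame)
    if arr.ndim == 3:
        if arr.shape[2] == 4:           # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise VideoFormatError(f"cannot interpret frame shape {arr.shape}")
    elif arr.ndim != 2:
        raise VideoFormatError(f"cannot interpret frame shape {arr.shape}")
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def read_video(path: str | os.PathLike, roi: RegionOfInterest | None = None,
               fps: float | None = None) -> FrameSequence:
    """Read a video file or frame stack into a :class:`FrameSequence`.

    Supports ``.npz`` stacks (keys ``frames`` and optionally ``fps``), a
    directory of image files (sorted by name), and any single file the imageio
    backends decode.  Color input is converted with BT.601 luma weights.  If
    ``roi`` is given the frames are cropped to it.

    ``fps`` overrides (or supplies, for containers without timing metadata)
    the nominal frame rate; the study's recordings averaged 38 fps.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"video path does not exist: {p}")

    rate = fps
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.is_file())
        if not files:
            raise VideoFormatError(f"no frames in directory {p}")
        import imageio.v3 as iio
        frames = [_to_gray(iio.imread(f)) for f in files]
    elif p.suffix == ".npz":
        with np.load(p) as data:
            if "frames" not in data:
                raise VideoFormatError(f"{p} has no 'frames' array")
            stack = data["frames"]
            if rate is None and "fps" in data:
                rate = float(data["fps"])
        if stack.ndim == 4:
            frames = [_to_gray(f) for f in stack]
        elif stack.ndim == 3:
            frames = [_to_gray(f) for f in stack]
        else:
            raise VideoFormatError(f"frame stack must be 3- or 4-D, got {stack.ndim}-D")
    else:
        import imageio.v3 as iio
        try:
            raw = iio.imread(p, index=None)
        except Exception as exc:  # backend-specific error types
            raise IOError(f"cannot decode video file {p}: {exc}") from exc
        if raw.ndim == 2 or (raw.ndim == 3 and raw.shape[-1] in (1, 3, 4)):
            raw = raw[None]
        frames = [_to_gray(f) for f in raw]

    if not frames:
        raise VideoFormatError(f"no frames decoded from {p}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise VideoFormatError(f"mixed frame sizes in {p}: {sorted(shapes)}")
    seq = FrameSequence(np.stack(frames), rate if rate is not None else 38.0)
    if roi is not None:
        seq = seq.crop(roi)
    return seq


def write_video(path: str | os.PathLike, seq: FrameSequence) -> None:
    """Write a frame sequence as an NPZ stack (lossless, round-trips exactly)."""
    np.savez_compressed(path, frames=seq.frames, fps=seq.fps)


def read_annotations(path: str | os.PathLike, total_frames: int) -> AnnotationTrack:
    """Read a CSV annotation track (``start_frame,end_frame,label``, 0-based,
    half-open) and clip intervals to ``[0, total_frames)``."""
    intervals: list[tuple[int, int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or (i == 0 and row[0].strip() == "start_frame"):
                continue
            if len(row) < 3:
                raise AnnotationFormatError(f"row {i}: expected start,end,label")
            try:
                start, end = int(row[0]), int(row[1])
            except ValueError as exc:
                raise AnnotationFormatError(f"row {i}: non-integer frame index") from exc
            label = row[2].strip()
            if label not in ALL_LABELS:
                raise AnnotationFormatError(f"row {i}: unknown label {label!r}")
            if start >= end:
                raise AnnotationFormatError(f"row {i}: start {start} >= end {end}")
            start = max(start, 0)
            end = min(end, total_frames)
            if start < end:
                intervals.append((start, end, label))
    return AnnotationTrack(intervals, total_frames)


def write_annotations(path: str | os.PathLike,
                      track: AnnotationTrack) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_frame", "end_frame", "label"])
        for s, e, lab in sorted(track.intervals):
            writer.writerow([s, e, lab])


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation between two equal-shape images.

    Each image has its mean removed; the correlation is the mean product
    divided by the product of the population standard deviations.  When either
    image has zero variance the value is 1.0 for bitwise-identical images and
    0.0 otherwise (flat identical frames are exactly the freeze signature).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    da = a - a.mean()
    db = b - b.mean()
    sa = np.sqrt(np.mean(da * da))
    sb = np.sqrt(np.mean(db * db))
    if sa == 0.0 or sb == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(np.mean(da * db) / (sa * sb))


def detect_frozen_frames(seq: FrameSequence,
                         ncc_threshold: float = 0.999) -> ValidityMask:
    """Flag frames repeating their predecessor (frozen video transfer).

    Frame ``n`` is invalid when the zero-normalized cross-correlation with
    frame ``n-1`` reaches ``ncc_threshold``; the first frame after each
    maximal frozen run is a reinitialization trigger.  Frame 0 is always
    valid.
    """
    n = len(seq)
    valid = np.ones(n, dtype=bool)
    frames = seq.frames
    for i in range(1, n):
        if normalized_cross_correlation(frames[i - 1], frames[i]) >= ncc_threshold:
            valid[i] = False
    reinit = []
    for i in range(1, n):
        if not valid[i] and (i + 1 == n or valid[i + 1]):
            if i + 1 < n:
                reinit.append(i + 1)
    return ValidityMask(valid, tuple(reinit))


def build_validity_mask(track: AnnotationTrack,
                        frozen: ValidityMask | None = None) -> ValidityMask:
    """Combine disturbance annotations and frozen-frame detection.

    A frame is valid iff it lies in no overlay / probe-repositioning / freeze
    interval and is not a detected frozen frame.  Reinit triggers are the
    union of frozen-run ends and the ends of probe-repositioning and freeze
    intervals (clipped to the recording).
    """
    n = track.total_frames
    if frozen is not None and len(frozen) != n:
        raise ValueError(
            f"frozen mask length {len(frozen)} != annotated frames {n}"
        )
    valid = np.ones(n, dtype=bool)
    reinit: set[int] = set()
    for s, e, lab in track.disturbance_intervals():
        valid[s:e] = False
        if lab in ("probe_reposition", "freeze") and e < n:
            reinit.add(e)
    if frozen is not None:
        valid &= frozen.valid
        reinit.update(frozen.reinit_frames)
    return ValidityMask(valid, tuple(sorted(reinit)))


def write_validity_mask(path: str | os.PathLike, mask: ValidityMask) -> None:
    reinit = set(mask.reinit_frames)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "valid", "reinit"])
        for i, v in enumerate(mask.valid):
            writer.writerow([i, int(v), int(i in reinit)])
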