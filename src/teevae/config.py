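"""Detector configuration: all tunables in one dataclass, YAML-loadable."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .io import RegionOfInterest


@dataclass
class DetectorConfig:
    """Every knob of the detection pipeline with its published default.

    The background model runs on the full frame by default while the ROI
    feeds only the cardiac mean-intensity signal; ``stats_roi`` restricts the
    model to a sub-region instead.
    """

    # cardiac-signal region (None -> centered 367x377, clipped to the frame)
    roi: RegionOfInterest | None = None
    # region the background model operates on (None -> full frame)
    stats_roi: RegionOfInterest | None = None

    filter_order: int = 2
    filter_critical_hz: float = 5.0
    filter_zero_phase: bool = False

    n_segments: int = 15
    init_window_s: float = 5.0
    period_band_s: tuple[float, float] = (0.4, 2.0)

    model_window: int = 30
    model_k: float = 3.0
    sigma_quantile: float = 0.65
    warmup_min_samples: int = 15
    pool_sigma_across_phases: bool = False

    median_window: int = 140
    floor_window: int = 140
    floor_quantile: float = 0.15
    alignment: str = "trailing"
    floor_source: str = "smoothed"

    merge_gap_frames: int = 38
    response_s: float = 3.0
    ncc_threshold: float = 0.999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key in ("roi", "stats_roi"):
            if kwargs.get(key) is not None:
                kwargs[key] = RegionOfInterest(**kwargs[key])
        if "period_band_s" in kwargs:
            kwargs["period_band_s"] = tuple(kwargs["period_band_s"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["period_band_s"] = list(self.period_band_s)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
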