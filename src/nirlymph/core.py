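"""Core data containers for the NIR lymphatic imaging pipeline.

The pipeline quantifies lymphatic pump function from near-infrared (NIR)
fluorescence recordings of collecting lymphatic vessels.  A lymphangion
contraction pushes a bolus of dye past a fixed region of interest, producing
a transient intensity spike ("packet") bounded by troughs.  These containers
carry the raw signals (traces, cuff-ramp recordings, image stacks) and the
derived quantities (packets, per-window metrics, pressure estimates,
area/swelling series).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "FluorescenceTrace",
    "RampRecording",
    "TailImageStack",
    "Packet",
    "PacketMetrics",
    "PumpingPressureResult",
    "AreaSeries",
    "SwellingSeries",
    "AnalysisConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input object violates its structural invariants."""


@dataclass
class FluorescenceTrace:
    """A sampled fluorescence intensity signal from one region of interest.

    Attributes
    ----------
    times : array of float
        Sample times in seconds, strictly increasing, uniformly spaced
        within a 1 % tolerance.
    intensities : array of float
        Fluorescence intensity in arbitrary units (a.u.), finite and >= 0.
    sample_rate_hz : float
        Nominal acquisition rate (frames per second).
    roi_label : str
        Free-text label of the region of interest.
    """

    times: np.ndarray
    intensities: np.ndarray
    sample_rate_hz: float
    roi_label: str = "roi"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValidationError("trace needs at least 2 samples")
        if self.intensities.shape != self.times.shape:
            raise ValidationError("times and intensities differ in length")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValidationError(f"time not strictly increasing at sample {row}")
        if not np.all(np.isfinite(self.intensities)):
            row = int(np.argmax(~np.isfinite(self.intensities)))
            raise ValidationError(f"non-finite intensity at sample {row}")
        if np.any(self.intensities < 0):
            row = int(np.argmax(self.intensities < 0))
            raise ValidationError(f"negative intensity at sample {row}")
        med = float(np.median(dt))
        if np.any(np.abs(dt - med) > 0.01 * med):
            row = int(np.argmax(np.abs(dt - med) > 0.01 * med)) + 1
            raise ValidationError(
                f"non-uniform sampling beyond 1% tolerance at sample {row}"
            )
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class RampRecording:
    """Paired cuff-pressure schedule and distal intensity from the
    pumping-pressure protocol (occlude at high pressure, step the cuff
    down, watch for flow resumption distal to the cuff)."""

    times: np.ndarray
    cuff_pressure_mmHg: np.ndarray
    distal_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cuff_pressure_mmHg = np.asarray(self.cuff_pressure_mmHg, dtype=float)
        self.distal_intensity = np.asarray(self.distal_intensity, dtype=float)
        n = self.times.size
        if self.cuff_pressure_mmHg.size != n or self.distal_intensity.size != n:
            raise ValidationError("ramp channels differ in length")
        if n < 2:
            raise ValidationError("ramp needs at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("ramp times not strictly increasing")
        if not np.all(np.isfinite(self.distal_intensity)):
            raise ValidationError("non-finite ramp intensity")
        if np.any(self.cuff_pressure_mmHg < 0):
            raise ValidationError("negative cuff pressure")


@dataclass
class TailImageStack:
    """Time-indexed grayscale frames with a binary tail mask."""

    frames: np.ndarray  # (n_frames, H, W)
    frame_times: np.ndarray
    tail_mask: np.ndarray  # (H, W) bool
    pixel_size: Optional[float] = None
    axis_angle_deg: float = 0.0  # tail long-axis orientation; 0 = horizontal

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, ...]
        if self.frames.ndim != 3:
            raise ValidationError("frames must be (n, H, W)")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.size != self.frames.shape[0]:
            raise ValidationError("frame_times length mismatch")
        if self.frame_times.size > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times not strictly increasing")
        self.tail_mask = np.asarray(self.tail_mask, dtype=bool)
        if self.tail_mask.shape != self.frames.shape[1:]:
            raise ValidationError("tail_mask shape does not match frames")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class Packet:
    """One detected fluorescence packet: a trough-bounded intensity pulse.

    ``baseline`` is the packet minimum intensity; ``amplitude`` is
    peak minus baseline; ``integral`` is the trapezoidal integral over
    [t_min, t_max] in the mode recorded by the detector.
    """

    t_min: float
    t_peak: float
    t_max: float
    baseline: float
    amplitude: float
    integral: float

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_peak < self.t_max):
            raise ValidationError(
                f"packet bounds must satisfy t_min < t_peak < t_max "
                f"({self.t_min}, {self.t_peak}, {self.t_max})"
            )
        if self.amplitude <= 0:
            raise ValidationError("packet amplitude must be > 0")
        if self.integral < 0:
            raise ValidationError("packet integral must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.t_max - self.t_min


@dataclass
class PacketMetrics:
    """Per-window summary of packet-based pump function."""

    n_packets: int
    transport: float  # time-normalized sum of packet integrals, a.u.
    frequency_per_min: float
    mean_amplitude: Optional[float]  # None when no packets were detected
    window_duration_s: float
    integration_mode: str = "above_min"

    def __post_init__(self) -> None:
        if self.window_duration_s <= 0:
            raise ValidationError("window_duration_s must be > 0")
        if self.n_packets < 0 or self.transport < 0 or self.frequency_per_min < 0:
            raise ValidationError("packet metrics must be >= 0")


@dataclass
class PumpingPressureResult:
    """Effective lymphatic pumping pressure from a cuff-ramp recording."""

    pressure_mmHg: float
    i_min: float
    i_max: float
    crossing_time_s: Optional[float]
    step_resolution_mmHg: float
    flags: tuple = ()


@dataclass
class AreaSeries:
    """Per-frame fraction of the tail area positive for fluorescence."""

    frame_times: np.ndarray
    positive_fraction: np.ndarray
    threshold_per_frame: np.ndarray
    tail_area_px: int

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.positive_fraction = np.asarray(self.positive_fraction, dtype=float)
        self.threshold_per_frame = np.asarray(self.threshold_per_frame, dtype=float)
        if self.tail_area_px <= 0:
            raise ValidationError("tail_area_px must be > 0")
        if np.any((self.positive_fraction < 0) | (self.positive_fraction > 1)):
            raise ValidationError("positive_fraction must lie in [0, 1]")


@dataclass
class SwellingSeries:
    """Tail swelling over time from 2-D projected masks.

    ``max_width`` is the maximum transverse pixel extent of the tail;
    ``circumference_proxy`` = pi * max_width assumes a circular
    cross-section (the pi factor cancels under baseline normalization).
    """

    days: np.ndarray
    max_width: np.ndarray
    circumference_proxy: np.ndarray
    normalized_circumference: np.ndarray
    baseline_day: float = 0.0

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.max_width = np.asarray(self.max_width, dtype=float)
        self.circumference_proxy = np.asarray(self.circumference_proxy, dtype=float)
        self.normalized_circumference = np.asarray(
            self.normalized_circumference, dtype=float
        )
        if self.baseline_day not in self.days:
            raise ValidationError("baseline day missing from series")
        ib = int(np.argmax(self.days == self.baseline_day))
        if abs(self.normalized_circumference[ib] - 1.0) > 1e-12:
            raise ValidationError("normalized circumference must be 1.0 at baseline")


@dataclass
class AnalysisConfig:
    """Tunable parameters for the analysis stages.

    Defaults follow the imaging protocol: 10 fps acquisition, functional
    metrics computed on the 5-20 min post-injection steady-state window,
    fluorescence area on the 0-10 min window.
    """

    steady_state_window_s: tuple = (300.0, 1200.0)
    area_window_s: tuple = (0.0, 600.0)
    # packet detection
    smooth_halfwidth_s: float = 1.0
    prominence_frac: float = 0.2
    noise_floor_sigma: float = 8.0
    min_peak_spacing_s: float = 2.0
    detrend_window_s: float = 30.0
    integration_mode: str = "above_min"  # or "raw"
    # pressure estimation
    pressure_median_filter_s: float = 1.0
    dynamic_range_floor: float = 0.25
    # image metrics
    threshold_method: str = "otsu"  # or "kmeans"
    swelling_threshold_frac: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.steady_state_window_s
        if not lo < hi:
            raise ValidationError("steady_state_window_s start must precede end")
        if self.swelling_threshold_frac <= 0:
            raise ValidationError("swelling_threshold_frac must be > 0")
        if self.integration_mode not in ("above_min", "raw"):
            raise ValidationError("integration_mode must be 'above_min' or 'raw'")
        if self.threshold_method not in ("otsu", "kmeans"):
            raise ValidationError("threshold_method must be 'otsu' or 'kmeans'")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["steady_state_window_s"] = list(d["steady_state_window_s"])
        d["area_window_s"] = list(d["area_window_s"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValidationError(f"unknown config fields: {sorted(bad)}")
        for key in ("steady_state_window_s", "area_window_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
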