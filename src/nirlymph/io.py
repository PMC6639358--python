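"""Readers and writers for the plain-text and TIFF formats the pipeline uses.

Formats
-------
* traces: 2-column CSV ``time_s,intensity`` (comma separator, ``.`` decimal,
  UTF-8, mandatory header), optional sidecar YAML of generator parameters
* ramp recordings: CSV ``time_s,cuff_mmHg,intensity``
* image stacks: multi-page TIFF + JSON ROI file with the tail polygon
  (0-based pixel coordinates, vertices in (x=col, y=row) order, origin at
  the top-left; even-odd fill rule)
* cohort tables: tidy CSV ``animal_id,group,day,metric,value``

Time is 0-based at the first sample; all analysis windows are half-open
[start, end) so abutting windows never double-count a sample.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    AnalysisConfig,
    FluorescenceTrace,
    RampRecording,
    TailImageStack,
    ValidationError,
)
from .simulate import rasterize_polygon

__all__ = [
    "read_trace",
    "write_trace",
    "read_ramp",
    "write_ramp",
    "read_stack",
    "write_stack",
    "read_cohort",
    "write_cohort",
    "crop_steady_state",
    "crop_window",
]

_TRACE_COLS = ("time_s", "intensity")
_RAMP_COLS = ("time_s", "cuff_mmHg", "intensity")


class TraceParseError(ValidationError):
    """Malformed trace/ramp CSV."""


def _read_csv(path, required) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing column(s) {missing}")
    for col in required:
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float, na_value=np.nan))]
        if len(bad):
            raise TraceParseError(
                f"{path}: non-finite {col} at row {int(bad[0]) + 2}"
            )  # +2: header line + 1-based
    return df


def read_trace(path, roi_label: Optional[str] = None) -> FluorescenceTrace:
    """Read a fluorescence trace CSV (columns ``time_s,intensity``)."""
    df = _read_csv(path, _TRACE_COLS)
    t = df["time_s"].to_numpy(dtype=float)
    y = df["intensity"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 3  # header + 1-based + offset row
        raise TraceParseError(f"{path}: time not strictly increasing at row {row}")
    fs = 1.0 / float(np.median(dt))
    return FluorescenceTrace(
        times=t,
        intensities=y,
        sample_rate_hz=fs,
        roi_label=roi_label or Path(str(path)).stem,
    )


def write_trace(trace: FluorescenceTrace, path, params=None) -> None:
    """Write a trace CSV; floats keep >=12 significant digits so a
    write/read round trip is lossless at double precision.  If ``params``
    (a dataclass) is given, a sidecar ``<path>.yaml`` records it."""
    df = pd.DataFrame(
        {"time_s": trace.times, "intensity": trace.intensities}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    if params is not None:
        side = Path(str(path)).with_suffix(".yaml")
        d = dataclasses.asdict(params)
        with open(side, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_yaml_safe(d), fh, sort_keys=True)


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_ramp(path) -> RampRecording:
    """Read a cuff-ramp CSV (columns ``time_s,cuff_mmHg,intensity``)."""
    df = _read_csv(path, _RAMP_COLS)
    return RampRecording(
        times=df["time_s"].to_numpy(dtype=float),
        cuff_pressure_mmHg=df["cuff_mmHg"].to_numpy(dtype=float),
        distal_intensity=df["intensity"].to_numpy(dtype=float),
    )


def write_ramp(rec: RampRecording, path) -> None:
    pd.DataFrame(
        {
            "time_s": rec.times,
            "cuff_mmHg": rec.cuff_pressure_mmHg,
            "intensity": rec.distal_intensity,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_stack(tiff_path, roi_path, frame_rate_hz: float = 10.0) -> TailImageStack:
    """Read a multi-page TIFF plus its JSON ROI file.

    The ROI JSON must carry ``tail_polygon`` (list of [x, y] vertices);
    optional keys: ``frame_rate_hz``, ``axis_angle_deg``, ``pixel_size``.
    Single-page TIFFs are accepted as 1-frame stacks; frame times come
    from the ROI file's frame rate (or ``frame_rate_hz``).
    """
    frames = tifffile.imread(str(tiff_path))
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None, ...]
    with open(roi_path, encoding="utf-8") as fh:
        roi = json.load(fh)
    if "tail_polygon" not in roi:
        raise ValidationError(f"{roi_path}: missing 'tail_polygon'")
    poly = np.asarray(roi["tail_polygon"], dtype=float)
    h, w = frames.shape[1:]
    # pixel centers sit at integer coordinates 0..w-1; a polygon enclosing
    # the whole frame legitimately extends half a pixel beyond them
    if np.any(poly[:, 0] < -1) or np.any(poly[:, 0] > w) \
            or np.any(poly[:, 1] < -1) or np.any(poly[:, 1] > h):
        raise ValidationError(f"{roi_path}: polygon outside image bounds")
    mask = rasterize_polygon((h, w), poly)
    fr = float(roi.get("frame_rate_hz", frame_rate_hz))
    times = np.arange(frames.shape[0]) / fr
    return TailImageStack(
        frames=frames,
        frame_times=times,
        tail_mask=mask,
        pixel_size=roi.get("pixel_size"),
        axis_angle_deg=float(roi.get("axis_angle_deg", 0.0)),
    )


def write_stack(stack: TailImageStack, tiff_path, roi_path,
                tail_polygon=None) -> None:
    """Write frames as multi-page TIFF and the ROI JSON.

    When ``tail_polygon`` is omitted, the bounding rectangle of the mask
    is written (adequate for rectangular masks; pass the true polygon for
    anything else)."""
    tifffile.imwrite(str(tiff_path), stack.frames, photometric="minisblack")
    if tail_polygon is None:
        rows, cols = np.nonzero(stack.tail_mask)
        if rows.size == 0:
            raise ValidationError("cannot derive polygon from empty mask")
        x0, x1 = float(cols.min()), float(cols.max())
        y0, y1 = float(rows.min()), float(rows.max())
        # half-pixel expansion so pixel centers on the hull are inside
        tail_polygon = [
            [x0 - 0.5, y0 - 0.5], [x1 + 0.5, y0 - 0.5],
            [x1 + 0.5, y1 + 0.5], [x0 - 0.5, y1 + 0.5],
        ]
        tail_polygon = [
            [min(max(x, -0.5), stack.frames.shape[2] - 0.5),
             min(max(y, -0.5), stack.frames.shape[1] - 0.5)]
            for x, y in tail_polygon
        ]
    fr = 1.0
    if stack.frame_times.size > 1:
        fr = 1.0 / float(np.median(np.diff(stack.frame_times)))
    roi = {
        "tail_polygon": [[float(x), float(y)] for x, y in tail_polygon],
        "frame_rate_hz": fr,
        "axis_angle_deg": stack.axis_angle_deg,
    }
    if stack.pixel_size is not None:
        roi["pixel_size"] = stack.pixel_size
    with open(roi_path, "w", encoding="utf-8") as fh:
        json.dump(roi, fh, indent=1)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = ["animal_id", "group", "day", "metric", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing column(s) {missing}")
    return df


def write_cohort(table: pd.DataFrame, path, header_comment: str = "") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        table.to_csv(fh, index=False, float_format="%.17g")


def crop_window(trace: FluorescenceTrace, start_s: float,
                end_s: float) -> FluorescenceTrace:
    """Retain samples with start <= t < end (half-open window)."""
    if start_s >= end_s:
        raise ValidationError("window start must precede end")
    sel = (trace.times >= start_s) & (trace.times < end_s)
    if sel.sum() < 2:
        raise ValidationError(
            f"trace does not cover steady-state window [{start_s}, {end_s})"
        )
    return FluorescenceTrace(
        times=trace.times[sel],
        intensities=trace.intensities[sel],
        sample_rate_hz=trace.sample_rate_hz,
        roi_label=trace.roi_label,
    )


def crop_steady_state(trace: FluorescenceTrace,
                      cfg: Optional[AnalysisConfig] = None) -> FluorescenceTrace:
    """Crop a trace to the steady-state analysis window (default 5-20 min
    post-injection), during which functional metrics are computed."""
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.steady_state_window_s
    return crop_window(trace, lo, hi)
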