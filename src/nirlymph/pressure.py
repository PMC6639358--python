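"""Effective lymphatic pumping pressure from a cuff-ramp recording.

Protocol: a cuff around the tail is inflated to 80 mmHg and held 5 min to
occlude flow, dropped to 55 mmHg, then stepped down to 0 in 2.5 mmHg
decrements of 5 s each, while distal fluorescence intensity is recorded.
The pumping pressure is the cuff pressure at which intensity passes halfway
between its occluded minimum and its restored maximum as flow resumes —
i.e. the maximal pressure the lymphangion chain can pump against.

Implementation choices (the published protocol does not pin them down):
the occluded minimum ``i_min`` is the mean over the high-pressure hold
(not the global minimum, avoiding pre-inflation transients); ``i_max`` is
the mean over the final lowest-pressure plateau; the crossing is the FIRST
time the 1 s-median-smoothed intensity rises above half-max during descent
("as flow resumed" implies onset), linearly interpolated between the two
bracketing pressure steps.  The 2.5 mmHg step resolution is reported so
results can be rounded back to protocol granularity.

All decision quantities are ratios of intensity differences, so the
estimate is invariant to affine rescaling a*I + b (a > 0) of the channel.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .core import AnalysisConfig, PumpingPressureResult, RampRecording, \
    ValidationError

__all__ = ["estimate_pumping_pressure"]


def _contiguous_run(mask: np.ndarray, first: bool) -> np.ndarray:
    """Indices of the first (or last) contiguous True run."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return idx
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    return runs[0] if first else runs[-1]


def estimate_pumping_pressure(
    ramp: RampRecording, cfg: Optional[AnalysisConfig] = None
) -> PumpingPressureResult:
    """Estimate effective pumping pressure from a cuff-ramp recording.

    Returns a :class:`PumpingPressureResult`; ``flags`` may contain
    ``"ceiling"`` (flow never occluded — pump exceeds the protocol range,
    pressure reported as the maximum ramp pressure), ``"no_flow_resumption"``
    (intensity never rises above half-max — pressure 0 mmHg, the
    no-detectable-pumping phenotype) or ``"degenerate_range"`` (dynamic
    range below the configured floor).
    """
    cfg = cfg or AnalysisConfig()
    t = ramp.times
    press = ramp.cuff_pressure_mmHg
    fs = 1.0 / float(np.median(np.diff(t)))

    ksize = max(1, int(round(cfg.pressure_median_filter_s * fs)))
    ksize += 1 - ksize % 2  # odd
    sm = ndimage.median_filter(ramp.distal_intensity, size=ksize, mode="nearest")

    p_max = float(press.max())
    p_min = float(press.min())
    hold = _contiguous_run(press >= p_max - 1e-9, first=True)
    plateau = _contiguous_run(press <= p_min + 1e-9, first=False)
    if hold.size == 0 or plateau.size == 0:
        raise ValidationError("ramp lacks an occlusion hold or final plateau")
    descent_start = int(hold[-1]) + 1
    if descent_start >= t.size:
        raise ValidationError("ramp contains no descending phase")

    i_min = float(sm[hold].mean())
    i_max = float(sm[plateau].mean())

    desc_press = press[descent_start:]
    steps = np.abs(np.diff(np.unique(desc_press)))
    step_res = float(np.median(steps)) if steps.size else 0.0

    # global span of the smoothed signal (median filtering has already
    # suppressed outliers; percentiles would hide short restored plateaus)
    glo, ghi = float(sm.min()), float(sm.max())
    grange = ghi - glo
    flags = []
    rel_range = (i_max - i_min) / grange if grange > 0 else 0.0
    if rel_range < cfg.dynamic_range_floor:
        flags.append("degenerate_range")
        if grange > 0 and (i_min - glo) / grange > 0.75:
            # intensity already high during the occlusion hold
            flags.append("ceiling")
            return PumpingPressureResult(
                pressure_mmHg=p_max, i_min=i_min, i_max=i_max,
                crossing_time_s=None, step_resolution_mmHg=step_res,
                flags=tuple(flags),
            )
        flags.append("no_flow_resumption")
        return PumpingPressureResult(
            pressure_mmHg=0.0, i_min=i_min, i_max=i_max,
            crossing_time_s=None, step_resolution_mmHg=step_res,
            flags=tuple(flags),
        )

    half = 0.5 * (i_min + i_max)
    above = sm[descent_start:] > half
    if not above.any():
        flags.append("no_flow_resumption")
        return PumpingPressureResult(
            pressure_mmHg=0.0, i_min=i_min, i_max=i_max,
            crossing_time_s=None, step_resolution_mmHg=step_res,
            flags=tuple(flags),
        )
    i_cross = descent_start + int(np.argmax(above))
    if i_cross == descent_start:
        flags.append("ceiling")
        return PumpingPressureResult(
            pressure_mmHg=p_max, i_min=i_min, i_max=i_max,
            crossing_time_s=float(t[i_cross]),
            step_resolution_mmHg=step_res, flags=tuple(flags),
        )
    y0, y1 = sm[i_cross - 1], sm[i_cross]
    frac = 0.0 if y1 == y0 else float((half - y0) / (y1 - y0))
    frac = min(max(frac, 0.0), 1.0)
    p0, p1 = press[i_cross - 1], press[i_cross]
    pressure = float(p0 + (p1 - p0) * frac)
    crossing_time = float(t[i_cross - 1] + (t[i_cross] - t[i_cross - 1]) * frac)
    pressure = min(max(pressure, 0.0), p_max)
    return PumpingPressureResult(
        pressure_mmHg=pressure, i_min=i_min, i_max=i_max,
        crossing_time_s=crossing_time, step_resolution_mmHg=step_res,
        flags=tuple(flags),
    )
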