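"""Fluorescent tail-area and swelling quantification from image stacks.

Percent-positive fluorescent area — the fraction of the tail's projected
area whose pixels exceed a cluster-derived threshold — measures how much
transport is carried by the initial (capillary) lymphatic network rather
than the collecting vessels.  Each frame is binarized with its own
threshold, computed by two-cluster (Otsu) histogram splitting over the
masked pixels, and the positive-pixel count is normalized by the tail area.

Swelling is tracked from per-day 2-D projected tail masks: the maximum
transverse width (pixel count) is converted to a circumference proxy under
a circular cross-section assumption (circumference = pi * width; the pi
factor cancels when normalizing to the pre-surgery baseline).
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .core import AnalysisConfig, AreaSeries, SwellingSeries, TailImageStack, \
    ValidationError

__all__ = [
    "DegenerateHistogramError",
    "otsu_threshold",
    "kmeans_threshold",
    "cluster_threshold",
    "fluorescence_area",
    "swelling_from_projection",
]


class DegenerateHistogramError(ValidationError):
    """All masked pixels share one intensity; no two-cluster split exists."""


def otsu_threshold(values: np.ndarray) -> float:
    """Two-cluster threshold minimizing intra-class variance (Otsu).

    Every split between consecutive distinct intensity values is scanned
    exhaustively; ties break toward the lower threshold.  The returned
    threshold is the midpoint between the two classes, so it lies strictly
    between them; pixels are positive when value > threshold.
    """
    vals = np.asarray(values).ravel()
    if vals.size == 0:
        raise DegenerateHistogramError("no pixels in mask")
    uniq, counts = np.unique(vals, return_counts=True)
    if uniq.size < 2:
        raise DegenerateHistogramError(
            "degenerate histogram: a single intensity value within the mask"
        )
    uniq = uniq.astype(float)
    w = counts.astype(float)
    cw = np.cumsum(w)                      # class-0 weight per split
    csum = np.cumsum(w * uniq)             # class-0 sum per split
    csq = np.cumsum(w * uniq ** 2)
    total_w, total_sum, total_sq = cw[-1], csum[-1], csq[-1]
    # split k: class0 = uniq[:k+1], class1 = uniq[k+1:]
    k = np.arange(uniq.size - 1)
    w0, s0, q0 = cw[k], csum[k], csq[k]
    w1, s1, q1 = total_w - w0, total_sum - s0, total_sq - q0
    intra = (q0 - s0 ** 2 / w0) + (q1 - s1 ** 2 / w1)
    best = int(np.argmin(intra))  # argmin takes the first (lowest) on ties
    return float(0.5 * (uniq[best] + uniq[best + 1]))


def kmeans_threshold(values: np.ndarray, max_iter: int = 200) -> float:
    """1-D two-means threshold (Lloyd iteration on the intensities).

    Deterministic: centers start at the masked min and max.  Returns the
    midpoint of the converged centers, snapped to the midpoint between the
    two adjacent distinct values it separates.
    """
    vals = np.asarray(values, dtype=float).ravel()
    uniq, counts = np.unique(vals, return_counts=True)
    if uniq.size < 2:
        raise DegenerateHistogramError(
            "degenerate histogram: a single intensity value within the mask"
        )
    c0, c1 = float(uniq[0]), float(uniq[-1])
    w = counts.astype(float)
    for _ in range(max_iter):
        cut = 0.5 * (c0 + c1)
        lowmask = uniq <= cut
        if not lowmask.any() or lowmask.all():
            break
        n0 = float(np.average(uniq[lowmask], weights=w[lowmask]))
        n1 = float(np.average(uniq[~lowmask], weights=w[~lowmask]))
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    cut = 0.5 * (c0 + c1)
    k = int(np.searchsorted(uniq, cut)) - 1
    k = min(max(k, 0), uniq.size - 2)
    return float(0.5 * (uniq[k] + uniq[k + 1]))


def cluster_threshold(image: np.ndarray, mask: Optional[np.ndarray] = None,
                      method: str = "otsu") -> float:
    """Cluster-based binarization threshold over the masked pixels."""
    img = np.asarray(image)
    vals = img[np.asarray(mask, dtype=bool)] if mask is not None else img
    if method == "otsu":
        return otsu_threshold(vals)
    if method == "kmeans":
        return kmeans_threshold(vals)
    raise ValidationError(f"unknown threshold method {method!r}")


def fluorescence_area(stack: TailImageStack,
                      cfg: Optional[AnalysisConfig] = None) -> AreaSeries:
    """Per-frame fraction of tail pixels positive for fluorescence.

    Frames outside the configured post-injection window (default 0-10 min,
    half-open) are excluded.  A frame whose masked histogram is degenerate
    (uniform intensity — nothing above background) records positive
    fraction 0 with a NaN threshold.
    """
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.area_window_s
    sel = (stack.frame_times >= lo) & (stack.frame_times < hi)
    if not sel.any():
        raise ValidationError("no frames within the area analysis window")
    mask = stack.tail_mask
    tail_area = int(mask.sum())
    if tail_area == 0:
        raise ValidationError("empty tail mask")
    times, fracs, thrs = [], [], []
    for ti, frame in zip(stack.frame_times[sel], stack.frames[sel]):
        vals = frame[mask]
        try:
            thr = cluster_threshold(vals, method=cfg.threshold_method)
            frac = float(np.count_nonzero(vals > thr)) / tail_area
        except DegenerateHistogramError:
            thr, frac = float("nan"), 0.0
        times.append(float(ti))
        thrs.append(thr)
        fracs.append(frac)
    return AreaSeries(
        frame_times=np.array(times),
        positive_fraction=np.array(fracs),
        threshold_per_frame=np.array(thrs),
        tail_area_px=tail_area,
    )


def _max_transverse_width(mask: np.ndarray, axis_angle_deg: float) -> int:
    """Maximum tail extent transverse to the tail axis, in pixels.

    axis 0 deg: tail runs horizontally, width = per-column pixel counts;
    90 deg: tail runs vertically, width = per-row counts."""
    m = np.asarray(mask, dtype=bool)
    ang = axis_angle_deg % 180.0
    if np.isclose(ang, 0.0):
        counts = m.sum(axis=0)
    elif np.isclose(ang, 90.0):
        counts = m.sum(axis=1)
    else:
        raise ValidationError(
            "only axis angles of 0 or 90 degrees are supported; rotate the "
            "masks upstream for oblique tails"
        )
    return int(counts.max())


def swelling_from_projection(masks: Dict[float, np.ndarray],
                             baseline_day: float = 0.0,
                             axis_angle_deg: float = 0.0,
                             axis_angles: Optional[Dict[float, float]] = None,
                             ) -> SwellingSeries:
    """Swelling series from per-day projected tail masks.

    ``masks`` maps day -> binary tail mask.  ``axis_angles`` optionally
    overrides the tail-axis angle per day (e.g. for a rotated acquisition).
    Swelling is reported as max transverse width, pi*width circumference
    proxy, and width normalized to the baseline day.
    """
    if baseline_day not in masks:
        raise ValidationError(f"missing baseline mask for day {baseline_day}")
    days = np.array(sorted(masks), dtype=float)
    widths = np.array([
        _max_transverse_width(
            masks[d],
            (axis_angles or {}).get(d, axis_angle_deg),
        )
        for d in days
    ], dtype=float)
    w0 = widths[int(np.argmax(days == baseline_day))]
    if w0 <= 0:
        raise ValidationError("baseline mask has zero width")
    return SwellingSeries(
        days=days,
        max_width=widths,
        circumference_proxy=np.pi * widths,
        normalized_circumference=widths / w0,
        baseline_day=baseline_day,
    )
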