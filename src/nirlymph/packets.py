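"""Packet detection and packet-based lymphatic function metrics.

A "packet" is the transient fluorescence spike produced when a lymphangion
contraction pushes a bolus of dye through the imaged region.  Detection
finds peaks in the (detrended, smoothed) signal and bounds each peak by the
nearest intensity troughs on either side.  From the detected packets:

* lymphatic fluorescence transport = (sum of packet integrals) / window
  duration — the time-normalized cumulative fluorescence transported, a
  proxy for actively pumped flow;
* packet frequency = 60 * n_packets / window duration (per minute);
* mean packet amplitude = mean(peak - packet minimum), a proxy for
  contraction amplitude / ejection fraction.

Two integration modes exist.  ``above_min`` (default) integrates
f(t) - baseline over each packet, making transport insensitive to residual
free-dye background; ``raw`` integrates f(t) itself.  The mode is stamped
into every output.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy.stats import norm

from .core import AnalysisConfig, FluorescenceTrace, Packet, PacketMetrics, \
    ValidationError

__all__ = [
    "detection_signal",
    "detect_packets",
    "packet_integral",
    "fluorescence_transport",
    "packet_frequency",
    "packet_amplitude",
    "compute_metrics",
    "packets_to_frame",
]


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def _detrend(x: np.ndarray, fs: float, window_s: float):
    """Rolling-median trend (captures bleaching drift, passes pulses).

    Returns (detrended, trend)."""
    if window_s <= 0:
        return x, np.zeros_like(x)
    size = _odd(max(3, int(round(window_s * fs))))
    size = min(size, _odd(x.size if x.size % 2 else x.size - 1))
    med = ndimage.median_filter(x, size=size, mode="nearest")
    return x - med, med


def _smooth(x: np.ndarray, fs: float, halfwidth_s: float) -> np.ndarray:
    h = int(round(halfwidth_s * fs))
    if h <= 0:
        return x
    k = 2 * h + 1
    if k > x.size:
        raise ValidationError("trace shorter than smoothing kernel")
    return ndimage.uniform_filter1d(x, size=k, mode="nearest")


def _nearest_local_min(s: np.ndarray, start: int, direction: int,
                       delta: float = 0.0, limit: Optional[int] = None) -> int:
    """Index of the nearest trough of ``s`` on one side of ``start``.

    Walks outward tracking the running minimum; the walk ends when the
    signal rises more than ``delta`` above it (hysteresis, so sub-noise
    wiggles on a pulse flank are not mistaken for troughs) or when
    ``limit`` (typically the adjacent peak) or an array edge is reached.
    With ``delta`` = 0 this is the nearest strict local minimum.
    """
    n = s.size
    stop = limit if limit is not None else (n - 1 if direction > 0 else 0)
    best = start
    i = start + direction
    while 0 <= i < n and (i - stop) * direction <= 0:
        if s[i] < s[best]:
            best = i
        elif s[i] > s[best] + delta:
            break
        i += direction
    return best


def detection_signal(trace: FluorescenceTrace,
                     cfg: Optional[AnalysisConfig] = None):
    """Preprocessed signal and peak criteria used by :func:`detect_packets`.

    Returns ``(smoothed, trend, prominence, distance_samples, noise_sd)``:
    the detrended+smoothed detection signal, the rolling-median trend, the
    prominence threshold (the configured fraction of the 5th-95th
    percentile range, floored at ``noise_floor_sigma`` times the smoothed
    noise SD estimated from successive differences), the minimum inter-peak
    spacing in samples, and the raw noise SD estimate.  Exposed so an
    exhaustive peak scan can be checked against the production detector.
    """
    cfg = cfg or AnalysisConfig()
    x = trace.intensities
    fs = 1.0 / trace.dt
    d, trend = _detrend(x, fs, cfg.detrend_window_s)
    s = _smooth(d, fs, cfg.smooth_halfwidth_s)
    lo, hi = np.percentile(s, [5.0, 95.0])
    # noise floor: successive-difference MAD estimate of the white-noise SD,
    # scaled to the smoothed signal; keeps low-duty-cycle traces (few pulses,
    # mostly baseline) from setting the prominence bar at noise level
    sigma = float(np.median(np.abs(np.diff(d)))) / (0.6745 * np.sqrt(2.0))
    ksmooth = 2 * int(round(cfg.smooth_halfwidth_s * fs)) + 1
    prominence = max(
        cfg.prominence_frac * float(hi - lo),
        cfg.noise_floor_sigma * sigma / np.sqrt(ksmooth),
    )
    distance = max(1, int(round(cfg.min_peak_spacing_s * fs)))
    return s, trend, prominence, distance, sigma


def detect_packets(trace: FluorescenceTrace,
                   cfg: Optional[AnalysisConfig] = None) -> List[Packet]:
    """Detect fluorescence packets in a (steady-state) trace.

    The signal is detrended by rolling-median subtraction, smoothed by a
    centered moving average, and peaks exceeding the prominence criterion
    (``prominence_frac`` of the 5th-95th percentile range) separated by at
    least ``min_peak_spacing_s`` are kept.  Packet bounds are the nearest
    local minima on either side of each peak; adjacent packets share their
    trough sample (which belongs to the left packet under the half-open
    convention).  Baseline, amplitude and integral are computed on the raw
    (undetrended) signal.  A constant trace yields an empty list.
    """
    cfg = cfg or AnalysisConfig()
    x = trace.intensities
    t = trace.times
    if trace.duration_s < 2.0:
        raise ValidationError("need at least 2 s of data for packet detection")
    fs = 1.0 / trace.dt
    s, trend, prominence, distance, sigma = detection_signal(trace, cfg)
    ksmooth = 2 * int(round(cfg.smooth_halfwidth_s * fs)) + 1
    if prominence <= 0:
        return []
    peaks, _ = signal.find_peaks(s, prominence=prominence, distance=distance)
    if peaks.size == 0:
        return []

    # equal-height plateau: the earliest sample is the peak
    adj = []
    for p in peaks:
        while p > 0 and s[p - 1] == s[p]:
            p -= 1
        adj.append(int(p))
    peaks = np.array(sorted(set(adj)))

    # troughs located on the smoothed signal, then refined to the raw-signal
    # minimum within one smoothing kernel (smoothing widens pulse support by
    # the kernel halfwidth); ties break toward the peak so flat inter-pulse
    # baselines yield troughs at the pulse boundaries
    # lightly median-filtered signal: used for trough/peak refinement and
    # peak height, where a raw extremum would carry extreme-value noise bias
    kmed = _odd(max(3, int(round(0.5 * fs))))
    xm = ndimage.median_filter(x, size=min(kmed, _odd(x.size - 1)),
                               mode="nearest")

    h = (ksmooth - 1) // 2
    sig_sm = sigma / np.sqrt(ksmooth)
    delta = 0.5 * sig_sm  # hysteresis for the trough walk
    lefts = np.empty(peaks.size, dtype=int)
    rights = np.empty(peaks.size, dtype=int)
    for k, p in enumerate(peaks):
        lim_l = peaks[k - 1] if k > 0 else 0
        lim_r = peaks[k + 1] if k + 1 < peaks.size else x.size - 1
        lsm = _nearest_local_min(s, p, -1, delta=delta, limit=lim_l)
        w0, w1 = max(0, lsm - h), min(p - 1, lsm + h)
        seg = xm[w0:w1 + 1]
        lefts[k] = w1 - int(np.argmin(seg[::-1]))  # last min = nearest to peak
        rsm = _nearest_local_min(s, p, +1, delta=delta, limit=lim_r)
        w0, w1 = max(p + 1, rsm - h), min(x.size - 1, rsm + h)
        rights[k] = w0 + int(np.argmin(xm[w0:w1 + 1]))  # first min
    # overlapping neighbors share the trough between their peaks
    for k in range(peaks.size - 1):
        if rights[k] > lefts[k + 1]:
            shared = peaks[k] + int(np.argmin(xm[peaks[k]:peaks[k + 1] + 1]))
            rights[k] = shared
            lefts[k + 1] = shared

    gap_cap = max(1, int(round(cfg.min_peak_spacing_s * fs)))

    packets: List[Packet] = []
    for k, (left, p, right) in enumerate(zip(lefts, peaks, rights)):
        if right - left < 2:
            continue
        # baseline = packet minimum intensity, estimated as the mean raw
        # intensity over the flanking inter-packet gaps (up to gap_cap
        # samples each side, never inside a neighboring packet): unbiased
        # under noise, unlike a raw min().  A margin around the trough
        # positions is excluded — troughs are argmin-selected, so their
        # neighborhoods are conditionally low and would bias the mean.
        margin = (kmed + 1) // 2 + 2
        lo_prev = rights[k - 1] if k > 0 else 0
        hi_next = lefts[k + 1] if k + 1 < peaks.size else x.size - 1
        gap_l = np.arange(max(lo_prev + margin, left - gap_cap),
                          left - margin + 1)
        gap_r = np.arange(right + margin,
                          min(hi_next - margin, right + gap_cap) + 1)
        gap = np.concatenate([gap_l, gap_r])
        if gap.size >= 8:
            baseline = float(x[gap].mean())
        else:
            # tightly packed packets leave no clean gap: use the minimum of
            # the smoothed signal, bias-corrected by the expected minimum of
            # the effective number of independent smoothed noise samples
            seg_s = s[left:right + 1]
            n_eff = max(1, int(round(seg_s.size / ksmooth)))
            corr = (float(norm.ppf((n_eff - 0.375) / (n_eff + 0.25)))
                    if n_eff > 1 else 0.0)
            baseline = float(trend[p] + seg_s.min() + corr * sig_sm)
        ipk = left + 1 + int(np.argmax(xm[left + 1:right]))
        amplitude = float(xm[ipk] - baseline)
        if amplitude <= 0:
            continue
        pkt = Packet(
            t_min=float(t[left]),
            t_peak=float(t[ipk]),
            t_max=float(t[right]),
            baseline=baseline,
            amplitude=amplitude,
            integral=0.0,
        )
        # noise around a marginal packet can push the above-baseline area
        # slightly negative; floor at zero (a packet never removes transport)
        pkt.integral = max(
            0.0, packet_integral(trace, pkt, mode=cfg.integration_mode)
        )
        packets.append(pkt)
    packets.sort(key=lambda pk: pk.t_min)
    return packets


def packet_integral(trace: FluorescenceTrace, packet: Packet,
                    mode: str = "above_min") -> float:
    """Trapezoidal integral of the signal over one packet, a.u.*s.

    ``raw`` integrates f(t) over [t_min, t_max]; ``above_min`` (default)
    integrates f(t) - baseline, the area above the packet minimum.
    """
    if mode not in ("above_min", "raw"):
        raise ValidationError(f"unknown integration mode {mode!r}")
    t = trace.times
    if packet.t_min < t[0] - 1e-9 or packet.t_max > t[-1] + 1e-9:
        raise ValidationError("packet bounds outside trace")
    i0 = int(np.searchsorted(t, packet.t_min - 1e-9))
    i1 = int(np.searchsorted(t, packet.t_max + 1e-9)) - 1
    seg_t = t[i0:i1 + 1]
    seg_y = trace.intensities[i0:i1 + 1].astype(float)
    if mode == "above_min":
        seg_y = seg_y - packet.baseline
    return float(np.trapezoid(seg_y, seg_t))


def fluorescence_transport(packets: List[Packet],
                           window_duration_s: float) -> float:
    """Lymphatic fluorescence transport: sum of packet integrals divided
    by the full analysis-window duration (a.u.).  No packets -> 0."""
    if window_duration_s <= 0:
        raise ValidationError("window_duration_s must be > 0")
    return float(sum(p.integral for p in packets)) / window_duration_s


def packet_frequency(packets: List[Packet], window_duration_s: float) -> float:
    """Packet (contraction) frequency, per minute."""
    if window_duration_s <= 0:
        raise ValidationError("window_duration_s must be > 0")
    return 60.0 * len(packets) / window_duration_s


def packet_amplitude(packets: List[Packet]) -> Optional[float]:
    """Mean packet amplitude (peak - packet minimum), a.u.

    Returns None for an empty list: "no contractions" is reported as
    missing, never as zero amplitude, so it cannot be conflated with
    "weak contractions"."""
    if not packets:
        return None
    return float(np.mean([p.amplitude for p in packets]))


def compute_metrics(trace: FluorescenceTrace,
                    cfg: Optional[AnalysisConfig] = None,
                    window_duration_s: Optional[float] = None) -> PacketMetrics:
    """Detect packets and summarize them for one analysis window.

    ``window_duration_s`` defaults to the sampled span of the trace
    (n_samples / sample rate), i.e. the full window over which packets
    were sought — not the summed packet durations.
    """
    cfg = cfg or AnalysisConfig()
    packets = detect_packets(trace, cfg)
    if window_duration_s is None:
        window_duration_s = len(trace) * trace.dt
    return PacketMetrics(
        n_packets=len(packets),
        transport=fluorescence_transport(packets, window_duration_s),
        frequency_per_min=packet_frequency(packets, window_duration_s),
        mean_amplitude=packet_amplitude(packets),
        window_duration_s=window_duration_s,
        integration_mode=cfg.integration_mode,
    )


def packets_to_frame(packets: List[Packet],
                     metrics: Optional[PacketMetrics] = None) -> pd.DataFrame:
    """Tabulate packets (one row each) plus an optional summary row."""
    rows = [
        {
            "row_type": "packet",
            "t_min": p.t_min, "t_peak": p.t_peak, "t_max": p.t_max,
            "baseline": p.baseline, "amplitude": p.amplitude,
            "integral": p.integral,
        }
        for p in packets
    ]
    df = pd.DataFrame(rows, columns=[
        "row_type", "t_min", "t_peak", "t_max", "baseline", "amplitude",
        "integral",
    ])
    if metrics is not None:
        summary = pd.DataFrame([{
            "row_type": "summary",
            "n_packets": metrics.n_packets,
            "transport": metrics.transport,
            "frequency_per_min": metrics.frequency_per_min,
            "mean_amplitude": metrics.mean_amplitude,
            "window_duration_s": metrics.window_duration_s,
            "mode": metrics.integration_mode,
        }])
        df = pd.concat([df, summary], ignore_index=True)
    return df
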