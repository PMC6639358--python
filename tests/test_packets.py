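"""Packet detection and transport metrics: closed-form and oracle checks."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from nirlymph.core import AnalysisConfig, FluorescenceTrace, Packet, \
    ValidationError
from nirlymph.packets import (
    compute_metrics,
    detect_packets,
    detection_signal,
    fluorescence_transport,
    packet_amplitude,
    packet_frequency,
    packet_integral,
)
from nirlymph.simulate import TraceSimParams, simulate_packet_trace


def make_trace(y, fs=10.0):
    y = np.asarray(y, dtype=float)
    return FluorescenceTrace(times=np.arange(y.size) / fs, intensities=y,
                             sample_rate_hz=fs)


class TestDetection:
    def test_constant_trace_yields_no_packets(self):
        trace = make_trace(np.full(600, 7.0))
        assert detect_packets(trace) == []

    def test_clean_train_recovers_all_pulses_and_bounds(self, clean_train):
        trace, truth = clean_train
        packets = detect_packets(trace)
        assert len(packets) == truth.n_packets == 5
        for pkt, c in zip(packets, truth.arrival_times):
            # trough times within one sample of the true pulse boundaries
            assert abs(pkt.t_min - (c - 2.0)) <= trace.dt + 1e-9
            assert abs(pkt.t_max - (c + 2.0)) <= trace.dt + 1e-9
            assert pkt.baseline == pytest.approx(20.0)

    def test_pulses_closer_than_min_spacing_merge_to_one(self):
        t = np.arange(0, 40, 0.1)
        y = np.full(t.size, 10.0)
        # two 1.2 s-wide triangles 1 s apart (< 2 s min spacing)
        for c, a in [(20.0, 5.0), (21.0, 4.0)]:
            tri = np.clip(1 - np.abs(t - c) / 0.6, 0, None) * a
            y += tri
        packets = detect_packets(make_trace(y))
        assert len(packets) == 1
        assert abs(packets[0].t_peak - 20.0) < 0.5  # more prominent retained

    def test_detection_is_idempotent_on_reconstruction(self, clean_train):
        trace, _ = clean_train
        packets = detect_packets(trace)
        y = np.full(len(trace), 20.0)
        t = trace.times
        for pkt in packets:
            w = pkt.t_max - pkt.t_min
            u = (t - pkt.t_peak) / w
            y += np.where(np.abs(u) <= 0.5,
                          0.5 * pkt.amplitude * (1 + np.cos(2 * np.pi * u)),
                          0.0)
        again = detect_packets(make_trace(y))
        assert len(again) == len(packets)

    def test_trace_shorter_than_two_seconds_rejected(self):
        with pytest.raises(ValidationError, match="2 s"):
            detect_packets(make_trace(np.arange(10.0)))

    def test_peaks_match_exhaustive_prominence_scan(self):
        """Detector peaks equal an independent brute-force local-maximum
        scan applying the same prominence + spacing rule."""
        cfg = AnalysisConfig()
        for seed in range(5):
            params = TraceSimParams(duration_s=150, packet_frequency_per_min=5,
                                    packet_amplitude=6, noise_sd=1.2,
                                    jitter_frac=0.1, seed=seed)
            trace, _ = simulate_packet_trace(params)
            assert len(trace) <= 2000
            s, _, prom, dist, _ = detection_signal(trace, cfg)
            # brute force: every strict local max, prominence by definition
            cands = [i for i in range(1, s.size - 1)
                     if s[i] > s[i - 1] and s[i] >= s[i + 1]]
            keep = []
            for i in cands:
                j = i - 1
                left_min = s[i]
                while j >= 0 and s[j] <= s[i]:
                    left_min = min(left_min, s[j])
                    j -= 1
                if j < 0:
                    left_base = left_min
                else:
                    left_base = left_min
                j = i + 1
                right_min = s[i]
                while j < s.size and s[j] <= s[i]:
                    right_min = min(right_min, s[j])
                    j += 1
                right_base = right_min
                if s[i] - max(left_base, right_base) >= prom:
                    keep.append(i)
            # spacing rule: keep taller peaks first
            keep.sort(key=lambda i: -s[i])
            chosen = []
            for i in keep:
                if all(abs(i - j) >= dist for j in chosen):
                    chosen.append(i)
            expected = np.sort(chosen)
            got, _ = find_peaks(s, prominence=prom, distance=dist)
            np.testing.assert_array_equal(got, expected)


class TestIntegral:
    def test_triangular_pulse_closed_form_area(self):
        fs = 10.0
        t = np.arange(0, 10, 1 / fs)
        y = np.clip(1 - np.abs(t - 5.0), 0, None) * 8.0  # base 2 s, height 8
        trace = make_trace(y, fs)
        pkt = Packet(t_min=4.0, t_peak=5.0, t_max=6.0, baseline=0.0,
                     amplitude=8.0, integral=0.0)
        area = packet_integral(trace, pkt, mode="above_min")
        assert abs(area - 8.0) <= 8.0 / fs  # within one sample's area

    def test_raw_mode_integrates_rectangle(self):
        trace = make_trace(np.full(31, 10.0))
        pkt = Packet(t_min=0.0, t_peak=1.0, t_max=2.0, baseline=10.0,
                     amplitude=1.0, integral=0.0)
        assert packet_integral(trace, pkt, mode="raw") == pytest.approx(20.0)
        assert packet_integral(trace, pkt, mode="above_min") == pytest.approx(0.0)

    def test_bounds_outside_trace_rejected(self):
        trace = make_trace(np.ones(50))
        pkt = Packet(t_min=3.0, t_peak=5.0, t_max=9.0, baseline=0.0,
                     amplitude=1.0, integral=0.0)
        with pytest.raises(ValidationError, match="outside trace"):
            packet_integral(trace, pkt)


class TestTransport:
    def test_no_packets_means_zero_transport(self):
        assert fluorescence_transport([], 60.0) == 0.0

    def test_single_packet_arithmetic(self):
        pkt = Packet(t_min=0.0, t_peak=1.0, t_max=2.0, baseline=0.0,
                     amplitude=8.0, integral=8.0)
        assert fluorescence_transport([pkt], 60.0) == pytest.approx(8.0 / 60.0)

    def test_duplicating_packets_doubles_transport(self, clean_train):
        trace, _ = clean_train
        packets = detect_packets(trace)
        t1 = fluorescence_transport(packets, 60.0)
        t2 = fluorescence_transport(packets + packets, 60.0)
        assert t2 == pytest.approx(2 * t1)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValidationError):
            fluorescence_transport([], 0.0)

    def test_above_min_transport_invariant_to_offset(self, clean_train):
        trace, _ = clean_train
        m0 = compute_metrics(trace)
        shifted = FluorescenceTrace(times=trace.times,
                                    intensities=trace.intensities + 37.0,
                                    sample_rate_hz=trace.sample_rate_hz)
        m1 = compute_metrics(shifted)
        assert m1.transport == pytest.approx(m0.transport, rel=1e-9)

    def test_raw_transport_shifts_by_offset_times_packet_time(self, clean_train):
        trace, _ = clean_train
        cfg = AnalysisConfig(integration_mode="raw")
        offset = 37.0
        p0 = detect_packets(trace, cfg)
        shifted = FluorescenceTrace(times=trace.times,
                                    intensities=trace.intensities + offset,
                                    sample_rate_hz=trace.sample_rate_hz)
        p1 = detect_packets(shifted, cfg)
        window = 60.0
        t0 = fluorescence_transport(p0, window)
        t1 = fluorescence_transport(p1, window)
        dur = sum(p.t_max - p.t_min for p in p0)
        assert t1 - t0 == pytest.approx(offset * dur / window, rel=1e-9)


class TestFrequencyAmplitude:
    def test_hundred_packets_in_900_seconds(self):
        pkt = Packet(t_min=0.0, t_peak=1.0, t_max=2.0, baseline=0.0,
                     amplitude=1.0, integral=1.0)
        assert packet_frequency([pkt] * 100, 900.0) == pytest.approx(6.667,
                                                                     abs=1e-3)
        assert packet_frequency([], 900.0) == 0.0

    def test_simulated_frequency_recovery_jitter_free(self):
        params = TraceSimParams(duration_s=900, packet_frequency_per_min=4.0,
                                jitter_frac=0.0, noise_sd=0.5, seed=1)
        trace, _ = simulate_packet_trace(params)
        m = compute_metrics(trace)
        assert m.frequency_per_min == pytest.approx(4.0, abs=0.07)

    def test_mean_amplitude_examples(self):
        def pkt(a):
            return Packet(t_min=0.0, t_peak=1.0, t_max=2.0, baseline=0.0,
                          amplitude=a, integral=1.0)
        assert packet_amplitude([pkt(8.0)]) == 8.0
        assert packet_amplitude([pkt(4.0), pkt(6.0)]) == 5.0

    def test_empty_amplitude_is_missing_not_zero(self):
        assert packet_amplitude([]) is None

    def test_amplitude_recovery_within_five_percent(self):
        params = TraceSimParams(duration_s=900, packet_frequency_per_min=6.0,
                                packet_amplitude=10.0, noise_sd=0.5,
                                jitter_frac=0.1, seed=3)
        trace, _ = simulate_packet_trace(params)
        m = compute_metrics(trace)
        assert m.n_packets >= 50
        assert m.mean_amplitude == pytest.approx(10.0, rel=0.05)
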