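"""Generator properties: known ground truth, analytic areas, determinism."""

import numpy as np
import pytest

from nirlymph.core import ValidationError
from nirlymph.simulate import (
    CohortSimParams,
    GroupSpec,
    RampSimParams,
    StackSimParams,
    TraceSimParams,
    default_ramp_schedule,
    pulse_area,
    rasterize_polygon,
    ramp_intensity_profile,
    simulate_cohort,
    simulate_packet_trace,
    simulate_ramp,
    simulate_tail_stack,
)


class TestPacketTrace:
    def test_no_contraction_limit_is_pure_baseline_decay(self):
        p = TraceSimParams(duration_s=100, packet_frequency_per_min=0.0,
                           noise_sd=0.0, seed=1)
        trace, truth = simulate_packet_trace(p)
        assert truth.n_packets == 0
        expected = p.baseline_intensity * np.exp(-p.bleach_rate_per_s * trace.times)
        np.testing.assert_allclose(trace.intensities, expected, rtol=1e-12)

    def test_control_frequency_pulse_count(self):
        # 6.7 contractions/min over 15 min of regular spacing
        p = TraceSimParams(duration_s=900, packet_frequency_per_min=6.7,
                           jitter_frac=0.0, noise_sd=0.0, seed=0)
        _, truth = simulate_packet_trace(p)
        assert truth.n_packets in (100, 101)

    @pytest.mark.parametrize("freq", [2.0, 5.0, 10.0])
    def test_pulse_count_matches_duration_times_frequency(self, freq):
        p = TraceSimParams(duration_s=600, packet_frequency_per_min=freq,
                           jitter_frac=0.0, noise_sd=0.0, seed=0)
        _, truth = simulate_packet_trace(p)
        assert abs(truth.n_packets - 600 * freq / 60) <= 1

    def test_zero_amplitude_trace_is_baseline_but_truth_has_arrivals(self):
        p = TraceSimParams(duration_s=120, packet_amplitude=0.0,
                           noise_sd=0.0, seed=2)
        trace, truth = simulate_packet_trace(p)
        assert truth.n_packets > 0
        expected = p.baseline_intensity * np.exp(-p.bleach_rate_per_s * trace.times)
        np.testing.assert_allclose(trace.intensities, expected, rtol=1e-12)

    @pytest.mark.parametrize("shape", ["raised_cosine", "triangular"])
    def test_ground_truth_area_matches_quadrature(self, shape):
        # analytic area A*w/2 vs trapezoid over the rendered pulse
        p = TraceSimParams(duration_s=60, packet_frequency_per_min=2.0,
                           packet_amplitude=6.0, packet_width_s=5.0,
                           noise_sd=0.0, bleach_rate_per_s=0.0,
                           jitter_frac=0.0, pulse_shape=shape, seed=0)
        trace, truth = simulate_packet_trace(p)
        assert truth.areas[0] == pulse_area(6.0, 5.0, shape) == 15.0
        c = truth.arrival_times[0]
        sel = np.abs(trace.times - c) <= 2.5
        quad = np.trapezoid(trace.intensities[sel] - 20.0, trace.times[sel])
        # quadrature error bounded by one sample's area
        assert abs(quad - truth.areas[0]) <= 6.0 * trace.dt

    def test_seed_reproducibility(self):
        p = TraceSimParams(duration_s=300, noise_sd=1.0, seed=7)
        t1, g1 = simulate_packet_trace(p)
        t2, g2 = simulate_packet_trace(p)
        np.testing.assert_array_equal(t1.intensities, t2.intensities)
        np.testing.assert_array_equal(g1.arrival_times, g2.arrival_times)

    def test_nyquist_constraint_rejected(self):
        with pytest.raises(ValidationError, match="Nyquist"):
            TraceSimParams(sample_rate_hz=0.3, packet_width_s=4.0)

    def test_width_must_fit_interval(self):
        with pytest.raises(ValidationError, match="inter-packet"):
            TraceSimParams(packet_frequency_per_min=20.0, packet_width_s=4.0)


class TestRamp:
    def test_default_schedule_follows_cuff_protocol(self):
        sched = default_ramp_schedule()
        assert sched[0] == (80.0, 300.0)
        descent = [p for p, _ in sched[1:]]
        assert descent[0] == 55.0 and descent[-1] == 0.0
        assert np.allclose(np.diff(descent), -2.5)
        assert all(h == 5.0 for _, h in sched[1:])

    def test_half_max_crossing_at_true_pressure(self):
        p = RampSimParams(true_pumping_pressure_mmHg=30.0, rise_width_mmHg=5.0,
                          noise_sd=0.0)
        mid = 0.5 * (p.min_intensity + p.max_intensity)
        assert ramp_intensity_profile(np.array([30.0]), p)[0] == pytest.approx(mid)
        assert ramp_intensity_profile(np.array([32.5]), p)[0] == p.min_intensity
        assert ramp_intensity_profile(np.array([27.5]), p)[0] == p.max_intensity

    def test_intensity_nonincreasing_in_pressure(self):
        p = RampSimParams(true_pumping_pressure_mmHg=25.0, noise_sd=0.0)
        pr = np.linspace(0, 80, 200)
        prof = ramp_intensity_profile(pr, p)
        assert np.all(np.diff(prof) <= 1e-12)  # falls as pressure rises

    def test_pump_stronger_than_cuff_rejected(self):
        with pytest.raises(ValidationError, match="never occluded"):
            RampSimParams(true_pumping_pressure_mmHg=90.0)

    def test_flat_dynamic_range_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            RampSimParams(true_pumping_pressure_mmHg=0.0,
                          min_intensity=50.0, max_intensity=50.0)

    def test_reproducible(self):
        p = RampSimParams(noise_sd=2.0, seed=5)
        r1, _ = simulate_ramp(p)
        r2, _ = simulate_ramp(p)
        np.testing.assert_array_equal(r1.distal_intensity, r2.distal_intensity)


class TestTailStack:
    def test_no_fluorescence_gives_zero_positive_fraction(self):
        p = StackSimParams(frame_count=3, capillary_fill_frac=0.0,
                           sinus_positions=(), vessel_half_width_px=0,
                           tubular_intensity_visible=100.0,
                           sinus_intensity=100.0, dilated_frames=(), seed=0)
        _, truth = simulate_tail_stack(p)
        assert np.all(truth == 0.0)

    def test_capillary_fill_fraction_recovered_in_truth(self):
        p = StackSimParams(frame_count=2, capillary_fill_frac=0.25,
                           sinus_positions=(), vessel_half_width_px=0,
                           dilated_frames=(), seed=1)
        stack, truth = simulate_tail_stack(p)
        tail_area = stack.tail_mask.sum()
        # exact pixel count: round(0.25 * tail_area) rendered pixels
        assert truth[0] == pytest.approx(round(0.25 * tail_area) / tail_area)
        assert abs(truth[0] - 0.25) < 0.01

    def test_dilated_frames_have_strictly_larger_positive_area(self):
        p = StackSimParams(frame_count=8, dilated_frames=(0, 1, 2, 3, 4),
                           capillary_fill_frac=0.1, seed=2)
        _, truth = simulate_tail_stack(p)
        assert truth[:5].min() > truth[5:].max()

    def test_zero_area_polygon_rejected(self):
        p = StackSimParams(tail_polygon=[(0, 0), (0, 0), (0, 0)])
        with pytest.raises(ValidationError, match="zero rasterized area"):
            simulate_tail_stack(p)

    def test_frames_are_uint16(self):
        stack, _ = simulate_tail_stack(StackSimParams(frame_count=1, seed=0))
        assert stack.frames.dtype == np.uint16


class TestCohort:
    @staticmethod
    def _normalize(table):
        from nirlymph.cohort import normalize_to_baseline
        return normalize_to_baseline(table)

    def test_null_group_normalizes_to_exactly_one(self):
        params = CohortSimParams(
            groups=[GroupSpec("sham", 3, 0.0, 4.0, 14.0, 0.0, 14.0)],
            timepoints_days=(0.0, 7.0, 14.0),
            between_animal_sd=0.0, measurement_sd=0.0, seed=0)
        table, _ = simulate_cohort(params)
        norm = self._normalize(table)
        assert np.allclose(norm["normalized_value"], 1.0)

    def test_dominant_ligation_nadir_value(self):
        # 92% transport loss at the day-7 nadir -> normalized 0.08
        params = CohortSimParams(
            groups=[GroupSpec("dom", 2, 0.45, 4.0, 28.0, 0.92, 90.0,
                              function_nadir_day=7.0)],
            timepoints_days=(0.0, 7.0),
            between_animal_sd=0.0, measurement_sd=0.0, seed=0)
        table, _ = simulate_cohort(params)
        norm = self._normalize(table)
        day7 = norm[(norm["metric"] == "transport") & (norm["day"] == 7.0)]
        assert np.allclose(day7["normalized_value"], 0.08)

    def test_every_animal_has_baseline_rows(self):
        table, _ = simulate_cohort(CohortSimParams(seed=3))
        counts = table[table["day"] == 0].groupby(
            ["animal_id", "metric"]).size()
        assert (counts == 1).all()

    def test_invalid_group_size_rejected(self):
        with pytest.raises(ValidationError):
            GroupSpec("bad", 0, 0.1, 4.0, 14.0, 0.1, 14.0)

    def test_timepoints_must_start_at_zero(self):
        with pytest.raises(ValidationError):
            CohortSimParams(timepoints_days=(2.0, 7.0))

    def test_reproducible(self):
        p = CohortSimParams(seed=11)
        t1, _ = simulate_cohort(p)
        t2, _ = simulate_cohort(p)
        assert t1.equals(t2)


class TestRasterize:
    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValidationError):
            rasterize_polygon((8, 8), [(0, 0), (4, 4)])

    def test_rectangle_pixel_count(self):
        # pixel centers strictly inside (0.5, 0.5)-(4.5, 2.5): cols 1-4, rows 1-2
        mask = rasterize_polygon(
            (8, 8), [(0.5, 0.5), (4.5, 0.5), (4.5, 2.5), (0.5, 2.5)])
        assert mask.sum() == 4 * 2
        assert mask[1:3, 1:5].all()
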