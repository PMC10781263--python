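"""Synthetic generator: amplifier gain, pulse model, front end, determinism."""

import numpy as np
import pytest
from dataclasses import replace

from ppgbench import (GroundTruth, PhysioParams, SensorConfig, Signal,
                      amplifier_gain, apply_front_end, generate_clean,
                      generate_dual_device, generate_rr, pulse_template)


class TestAmplifierGain:
    @pytest.mark.parametrize("r6, r5, expected", [
        (3.3e6, 1e4, 331.0),   # stock resistor values
        (0.0, 1e4, 1.0),       # zero feedback: unity gain
        (1e6, 1e4, 101.0),
        (1e7, 1e4, 1001.0),
    ])
    def test_noninverting_gain_formula(self, r6, r5, expected):
        assert amplifier_gain(r6, r5) == pytest.approx(expected)

    def test_nonpositive_r5_rejected(self):
        with pytest.raises(ValueError):
            amplifier_gain(1e6, 0.0)


class TestPulseTemplate:
    def test_systolic_peak_value_without_diastolic_lobe(self):
        p = PhysioParams(diastolic_amp_fraction=0.0, systolic_amp=2.5)
        assert pulse_template(0.25, p) == pytest.approx(2.5)

    def test_far_tail_is_negligible(self):
        p = PhysioParams(diastolic_amp_fraction=0.0)
        far = 0.25 + 6 * p.pulse_width_fraction
        assert pulse_template(far, p) < 1e-5 * p.systolic_amp

    def test_argmax_at_systolic_center_by_grid_search(self):
        # brute-force oracle: dense grid over one beat; without a
        # diastolic lobe the maximum is exactly the systolic center, with
        # it the maximum shifts by well under one lobe width
        grid = np.arange(0.0, 1.0, 1e-4)
        p0 = PhysioParams(diastolic_amp_fraction=0.0)
        assert grid[np.argmax(pulse_template(grid, p0))] \
            == pytest.approx(0.25, abs=1e-4)
        p = PhysioParams()
        argmax = grid[np.argmax(pulse_template(grid, p))]
        assert abs(argmax - 0.25) < p.pulse_width_fraction / 2


class TestGenerateRR:
    def test_degenerate_jitter_gives_exact_intervals(self):
        p = PhysioParams(mean_hr_bpm=60.0, sdnn_s=0.0, duration_s=10.0)
        assert np.allclose(generate_rr(p), 1.0)
        p75 = PhysioParams(mean_hr_bpm=75.0, sdnn_s=0.0, duration_s=8.0)
        assert np.allclose(generate_rr(p75), 0.8)

    def test_interval_sd_matches_requested_sdnn(self):
        # law-of-large-numbers check at n ~ 10000 beats
        p = PhysioParams(mean_hr_bpm=60.0, sdnn_s=0.05, duration_s=10000.0,
                         seed=3)
        rr = generate_rr(p)
        assert rr.size >= 9000
        assert 0.045 <= rr.std(ddof=0) <= 0.055

    def test_intervals_cover_duration(self):
        p = PhysioParams(mean_hr_bpm=70.0, duration_s=60.0, seed=2)
        assert generate_rr(p).sum() >= 60.0


class TestGenerateClean:
    def test_metronomic_peaks_equal_height_and_spacing(self):
        p = PhysioParams(mean_hr_bpm=60.0, sdnn_s=0.0, noise_sd=0.0,
                         resp_amp=0.0, duration_s=20.0)
        sig, truth = generate_clean(p, 1000.0)
        assert np.allclose(np.diff(truth.peak_times_s), 1.0)
        heights = sig.samples[(truth.peak_times_s * 1000).astype(int)]
        assert np.ptp(heights) < 1e-6

    def test_peak_count_at_60_bpm_over_120_s(self, clean_60bpm):
        _, _, truth = clean_60bpm
        assert len(truth.peak_times_s) == 120

    def test_true_peaks_sit_on_local_maxima(self, clean_60bpm):
        # brute-force oracle: local maximum within +-10 ms of each truth peak
        _, sig, truth = clean_60bpm
        x = sig.samples
        for t in truth.peak_times_s:
            i = int(round(t * 1000))
            lo, hi = max(0, i - 10), min(len(x), i + 11)
            j = lo + int(np.argmax(x[lo:hi]))
            assert abs(j - i) <= 10


class TestFrontEnd:
    def _truth(self, n):
        return GroundTruth(peak_times_s=np.array([0.1]), rr_s=np.array([1.0]))

    def test_linear_regime_is_round_of_gain_times_input_plus_offset(self):
        sensor = SensorConfig(r6_ohm=0.0, adc_bits=10, site_gain=1.0)
        x = np.linspace(0.0, 50.0, 100)
        sig = Signal(x, 1000.0)
        out, truth = apply_front_end(sig, sensor, self._truth(100))
        assert not truth.saturated_mask.any()
        np.testing.assert_array_equal(out.samples, np.rint(x + 511.5))

    def test_constant_drive_above_ceiling_hard_clips(self):
        sensor = SensorConfig(adc_bits=10, site_gain=1.0)
        sig = Signal(np.full(50, 1e5), 1000.0)
        out, truth = apply_front_end(sig, sensor, self._truth(50))
        assert (out.samples == 1023).all()
        assert truth.saturated_mask.all()
        assert truth.clip_level == 1023

    def test_saturated_sample_distribution_has_spread(self):
        # saturation is gradual: minimum well below the mean among
        # saturated samples of a sinusoid driven into the knee
        sensor = SensorConfig(adc_bits=10, site_gain=1.0)
        t = np.arange(5000) / 1000.0
        sig = Signal(1.3 * np.sin(2 * np.pi * 1.0 * t), 1000.0)
        out, truth = apply_front_end(sig, sensor, self._truth(5000))
        sat = out.samples[truth.saturated_mask]
        assert sat.size > 0
        assert sat.min() < sat.mean() - 1.0

    @pytest.mark.parametrize("bits", [10, 23])
    def test_quantized_output_respects_adc_range(self, bits):
        sensor = SensorConfig(adc_bits=bits, site_gain=1.0)
        rng = np.random.default_rng(0)
        sig = Signal(rng.normal(0.0, 5.0, 2000), 1000.0)
        out, _ = apply_front_end(sig, sensor, self._truth(2000))
        assert out.samples.min() >= 0
        assert out.samples.max() <= (1 << bits) - 1
        assert out.samples.dtype.kind == "i"

    def test_saturated_fraction_monotone_in_feedback_resistance(self):
        p = PhysioParams(duration_s=30.0, seed=4)
        phys, truth = generate_clean(p, 1000.0)
        fractions = []
        for r6 in (1e6, 2e6, 3.3e6, 5e6, 1e7):
            sensor = SensorConfig(r6_ohm=r6, adc_bits=10, site_gain=2.0)
            _, t = apply_front_end(phys, sensor, truth)
            fractions.append(t.saturated_mask.mean())
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] > fractions[0]


class TestDualDevice:
    def test_same_seed_is_bit_identical(self):
        p = PhysioParams(duration_s=15.0)
        sensors = (SensorConfig(label="A"), SensorConfig(label="B"))
        s1 = generate_dual_device(p, sensors, offset_samples=50, seed=9)
        s2 = generate_dual_device(p, sensors, offset_samples=50, seed=9)
        for r1, r2 in ((s1.recording_a, s2.recording_a),
                       (s1.recording_b, s2.recording_b)):
            for name in r1.signals:
                np.testing.assert_array_equal(r1.signals[name].samples,
                                              r2.signals[name].samples)
            np.testing.assert_array_equal(r1.aux_sync.samples,
                                          r2.aux_sync.samples)

    def test_zero_offset_aux_edges_coincide(self):
        from ppgbench import detect_sync_pulse
        p = PhysioParams(duration_s=15.0)
        sensors = (SensorConfig(label="A"), SensorConfig(label="B"))
        sim = generate_dual_device(p, sensors, offset_samples=0, seed=2)
        ea = detect_sync_pulse(sim.recording_a.aux_sync)
        eb = detect_sync_pulse(sim.recording_b.aux_sync)
        assert ea == pytest.approx(eb)

    def test_truth_peaks_shift_by_injected_offset(self):
        p = PhysioParams(duration_s=15.0, sdnn_s=0.0, noise_sd=0.0)
        sensors = (SensorConfig(label="A"), SensorConfig(label="B"))
        sim = generate_dual_device(p, sensors, offset_samples=250, seed=2)
        # shared beats appear 0.25 s later in B's timebase
        n = min(len(sim.truth_a.peak_times_s), len(sim.truth_b.peak_times_s))
        deltas = sim.truth_b.peak_times_s[:n] - sim.truth_a.peak_times_s[:n]
        assert np.allclose(deltas[np.abs(deltas) < 0.5], 0.25)


class TestHRRecovery:
    def test_pipeline_recovers_generated_mean_hr_within_one_bpm(self):
        # parameter-recovery contract on clean signals
        from ppgbench import PeakSet, detect_peaks, hr_from_peaks
        for hr in (60.0, 90.0):
            p = PhysioParams(mean_hr_bpm=hr, noise_sd=0.02, duration_s=60.0,
                             seed=int(hr))
            sig, truth = generate_clean(p, 1000.0)
            peaks, _ = detect_peaks(sig)
            rep = hr_from_peaks(peaks)
            assert abs(rep.mean_hr_bpm - hr) < 1.0
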