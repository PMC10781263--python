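"""Bandpass filtering and two-moving-average systolic-peak detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from ppgbench import (ElgendiParams, FilterSpec, PeakSet, PhysioParams,
                      Signal, bandpass, detect_peaks, elgendi_peaks,
                      find_onsets, generate_clean, match_peaks)
from ppgbench.detection import _centered_ma, _odd_window, interest_blocks

FS = 1000.0


class TestBandpass:
    def test_dc_is_rejected(self):
        sig = Signal(np.full(10_000, 700.0), FS)
        out = bandpass(sig)
        assert np.abs(out[2000:-2000]).max() < 1e-6 * 700.0

    def test_midband_tone_passes_at_analog_prototype_gain(self):
        # oracle: analog Butterworth magnitude response, squared for the
        # forward-backward application
        t = np.arange(20_000) / FS
        sig = Signal(np.sin(2 * np.pi * 4.0 * t), FS)
        out = bandpass(sig)[2000:-2000]
        b, a = sps.butter(4, [2 * np.pi * 1.0, 2 * np.pi * 8.0],
                          btype="bandpass", analog=True)
        _, h = sps.freqs(b, a, worN=[2 * np.pi * 4.0])
        expected = np.abs(h[0]) ** 2
        assert np.abs(out).max() == pytest.approx(expected, rel=0.05)

    def test_sub_band_tone_strongly_attenuated(self):
        t = np.arange(40_000) / FS
        sig = Signal(np.sin(2 * np.pi * 0.1 * t), FS)
        out = bandpass(sig)[5000:-5000]
        assert np.abs(out).max() < 1.0 / 20.0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(Signal(np.ones(100), 10.0))

    def test_output_length_equals_input_length(self, clean_70bpm):
        _, sig, _ = clean_70bpm
        assert bandpass(sig).size == len(sig)


class TestElgendiPeaks:
    def test_all_zero_signal_yields_no_peaks(self):
        assert len(elgendi_peaks(np.zeros(5000), FS)) == 0

    def test_empty_input_yields_empty_peakset(self):
        assert len(elgendi_peaks(np.array([]), FS)) == 0

    def test_single_isolated_pulse_found_at_its_maximum(self):
        t = np.arange(4000) / FS
        x = np.exp(-0.5 * ((t - 2.0) / 0.08) ** 2)
        peaks = elgendi_peaks(x, FS)
        assert len(peaks) == 1
        assert peaks.indices[0] == np.argmax(x)

    def test_clean_60bpm_recovers_every_beat_within_10_ms(self, clean_60bpm):
        _, sig, truth = clean_60bpm
        peaks, _ = detect_peaks(sig)
        assert len(peaks) == len(truth.peak_times_s) == 120
        errors = np.abs(peaks.times_s - truth.peak_times_s)
        assert errors.max() <= 0.010

    def test_peaks_strictly_increasing_and_separated(self, clean_70bpm):
        _, sig, _ = clean_70bpm
        peaks, _ = detect_peaks(sig)
        gaps = np.diff(peaks.indices)
        assert (gaps > 0).all()
        assert gaps.min() >= int(0.18 * FS)

    def test_detection_sensitivity_and_precision_on_clean_midrange_hr(self):
        for hr in (60, 90, 120):
            p = PhysioParams(mean_hr_bpm=float(hr), duration_s=120.0, seed=hr)
            sig, truth = generate_clean(p, FS)
            peaks, _ = detect_peaks(sig)
            m = match_peaks(PeakSet.from_times(truth.peak_times_s, FS), peaks)
            assert m.sensitivity >= 0.99, hr
            assert m.precision >= 0.99, hr

    def test_clipping_systolic_lobes_reduces_sensitivity(self, clean_60bpm):
        # flat-topping >= 50% of each systolic lobe displaces the block
        # argmax off the true peak: detection degrades on the same seed
        _, sig, truth = clean_60bpm
        truth_set = PeakSet.from_times(truth.peak_times_s, FS)
        m_clean = match_peaks(truth_set, detect_peaks(sig)[0])
        clipped = Signal(np.minimum(sig.samples, 0.5 * sig.samples.max()), FS)
        m_clip = match_peaks(truth_set, detect_peaks(clipped)[0])
        assert m_clip.sensitivity < m_clean.sensitivity


def brute_force_blocks(filtered, fs, params=ElgendiParams()):
    """Pointwise reference: evaluate both moving averages per sample and
    enumerate maximal runs of MA_peak > THR1, keeping runs >= W1 wide."""
    sq = np.maximum(np.asarray(filtered, float), 0.0) ** 2
    w1 = _odd_window(params.w1_s, fs)
    w2 = _odd_window(params.w2_s, fs)
    offset = params.beta * sq.mean()

    def ma_at(i, width):
        half = width // 2
        padded = np.pad(sq, half, mode="reflect")
        return padded[i:i + width].mean()

    active = [ma_at(i, w1) > ma_at(i, w2) + offset for i in range(sq.size)]
    blocks, start = [], None
    for i, a in enumerate(active + [False]):
        if a and start is None:
            start = i
        elif not a and start is not None:
            if i - start >= max(1, round(params.w1_s * fs)):
                blocks.append((start, i))
            start = None
    return blocks


class TestBlockEquivalence:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_blocks_match_pointwise_reference_on_short_signals(self, seed):
        rng = np.random.default_rng(seed)
        fs = 250.0
        n = int(rng.integers(300, 2500))  # up to 10 s at 250 Hz
        x = rng.normal(0.0, 1.0, n)
        # add a few pulse-like bumps so blocks actually form
        for c in rng.uniform(0, n, 3):
            t = np.arange(n)
            x += 3.0 * np.exp(-0.5 * ((t - c) / (0.08 * fs)) ** 2)
        assert interest_blocks(x, fs) == brute_force_blocks(x, fs)


class TestFindOnsets:
    def test_onset_is_the_brute_force_minimum_before_each_peak(self):
        rng = np.random.default_rng(2)
        t = np.arange(5000) / FS
        x = (np.exp(-0.5 * ((t - 1.0) / 0.08) ** 2)
             + np.exp(-0.5 * ((t - 2.0) / 0.08) ** 2)
             + 0.01 * rng.normal(size=t.size))
        peaks = PeakSet(np.array([1000, 2000]), FS)
        onsets = find_onsets(x, peaks)
        w2 = int(0.69 * FS)
        assert onsets[0] == 1000 - w2 + np.argmin(x[1000 - w2:1001])
        assert onsets[1] == 1001 + np.argmin(x[1001:2001])

    def test_two_identical_pulses_give_equidistant_onsets(self):
        t = np.arange(4000) / FS
        x = (np.exp(-0.5 * ((t - 1.2) / 0.08) ** 2)
             + np.exp(-0.5 * ((t - 2.4) / 0.08) ** 2))
        peaks = PeakSet(np.array([1200, 2400]), FS)
        onsets = find_onsets(x, peaks)
        assert len(onsets) == 2
        # second onset sits at the symmetric midpoint valley
        assert abs((2400 - onsets[1]) - (2400 - 1200) / 2) <= 1

    def test_empty_peakset_gives_empty_onsets(self):
        assert find_onsets(np.zeros(100), PeakSet(np.array([]), FS)).size == 0


class TestParams:
    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError):
            ElgendiParams(w1_s=0.7, w2_s=0.5)

    def test_filter_band_ordering_enforced(self):
        with pytest.raises(ValueError):
            FilterSpec(band=(8.0, 1.0))

    def test_moving_average_window_forced_odd(self):
        assert _odd_window(0.18, FS) % 2 == 1
        assert _odd_window(0.69, FS) % 2 == 1

    def test_centered_moving_average_of_constant_is_identity(self):
        x = np.full(100, 3.0)
        np.testing.assert_allclose(_centered_ma(x, 11), x)
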