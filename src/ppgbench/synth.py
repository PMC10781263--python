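"""Synthetic PPG generation with known ground truth.

The generator emulates a two-device, multi-site PPG acquisition: a
quasi-periodic pulse train (two-Gaussian beat template: systolic lobe plus
a smaller, delayed diastolic lobe), beat-to-beat interval jitter,
respiratory baseline wander, additive Gaussian noise and optional motion
artifact bursts.  The analog front end applies transimpedance-amplifier
gain ``Av = 1 + R6/R5``, a site-dependent amplitude factor, a mid-range DC
bias, soft-knee compression approaching the ADC ceiling, hard clipping at
``2**bits - 1`` and integer quantization.  Every stage records ground truth
(true systolic peak times, beat intervals, per-sample saturation mask) so
downstream detection and evaluation can be validated without real
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .signal_io import Recording, Signal

__all__ = [
    "SensorConfig",
    "PhysioParams",
    "GroundTruth",
    "DualDeviceResult",
    "amplifier_gain",
    "pulse_template",
    "generate_rr",
    "generate_clean",
    "apply_front_end",
    "generate_dual_device",
    "calibration_drive",
]

MIN_RR_S = 0.3  # physiological floor for a beat interval


def amplifier_gain(r6_ohm: float, r5_ohm: float) -> float:
    """Closed-loop gain of the non-inverting transimpedance stage.

    ``Av = 1 + R6/R5``.  With the stock resistor values R6 = 3.3 MOhm and
    R5 = 10 kOhm the gain is 331; swapping R6 retunes the sensor.
    """
    if r5_ohm <= 0:
        raise ValueError(f"r5_ohm must be positive, got {r5_ohm}")
    if r6_ohm < 0:
        raise ValueError(f"r6_ohm must be non-negative, got {r6_ohm}")
    return 1.0 + r6_ohm / r5_ohm


@dataclass(frozen=True)
class SensorConfig:
    """Analog front end + ADC of one fine-tuned sensor.

    ``ceiling_knee_fraction`` sets where soft compression starts, as a
    fraction of the full ADC range; above it the response is quadratically
    compressed into the ceiling before the hard clip, so saturation is
    gradual rather than instantaneous.
    """

    r6_ohm: float = 3.3e6
    r5_ohm: float = 1e4
    adc_bits: int = 10
    site_gain: float = 1.0
    ceiling_knee_fraction: float = 0.9
    label: str = "G_def"
    site: str = "finger"
    device: str = "synthetic"

    def __post_init__(self) -> None:
        if self.r5_ohm <= 0:
            raise ValueError("r5_ohm must be positive")
        if self.r6_ohm < 0:
            raise ValueError("r6_ohm must be non-negative")
        if not 0 < self.ceiling_knee_fraction <= 1:
            raise ValueError("ceiling_knee_fraction must be in (0, 1]")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be a positive integer")

    @property
    def gain(self) -> float:
        return amplifier_gain(self.r6_ohm, self.r5_ohm)

    @property
    def adc_max(self) -> int:
        return (1 << self.adc_bits) - 1


@dataclass(frozen=True)
class PhysioParams:
    """Physiological simulation parameters.

    Amplitudes are in normalized physiological units (systolic peak = 1 by
    default) before the front end; fractions are of one beat interval.
    """

    mean_hr_bpm: float = 70.0
    sdnn_s: float = 0.03
    systolic_amp: float = 1.0
    diastolic_amp_fraction: float = 0.35
    diastolic_delay_fraction: float = 0.18
    pulse_width_fraction: float = 0.08
    resp_rate_hz: float = 0.25
    resp_amp: float = 0.05
    noise_sd: float = 0.01
    artifact_rate_per_min: float = 0.0
    artifact_amp: float = 0.0
    artifact_start_s: float = 0.0
    duration_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 20 < self.mean_hr_bpm < 250:
            raise ValueError("mean_hr_bpm must be in (20, 250)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("systolic_amp", "diastolic_amp_fraction", "resp_amp",
                     "noise_sd", "artifact_amp", "sdnn_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Simulation ground truth used to score the analysis pipeline."""

    peak_times_s: np.ndarray
    rr_s: np.ndarray
    saturated_mask: np.ndarray | None = None
    clip_level: int | None = None


SYSTOLIC_CENTER = 0.25  # systolic peak position as a fraction of the beat
REF_BEAT_S = 1.0  # reference beat anchoring the template's time fractions


def pulse_template(t_frac: float | np.ndarray, params: PhysioParams
                   ) -> np.ndarray:
    """Single-beat waveform evaluated at beat fraction ``t_frac`` in [0, 1).

    Sum of two Gaussian lobes: the systolic lobe (amplitude
    ``systolic_amp``, center 0.25 of the beat, width
    ``pulse_width_fraction``) and a diastolic lobe delayed by
    ``diastolic_delay_fraction`` with relative amplitude
    ``diastolic_amp_fraction``.  For any diastolic fraction < 1 the global
    maximum is the systolic lobe.

    Fractions refer to the 1 s reference beat.  When beats are rendered at
    other rates the lobe widths and the diastolic delay keep their
    absolute durations (systole shortens far less than diastole as heart
    rate rises) while the systolic center stays at 0.25 of the actual
    beat — see :func:`generate_clean`.
    """
    t = np.asarray(t_frac, float)
    w = params.pulse_width_fraction
    sys_lobe = np.exp(-0.5 * ((t - SYSTOLIC_CENTER) / w) ** 2)
    dia_center = SYSTOLIC_CENTER + params.diastolic_delay_fraction
    dia_lobe = params.diastolic_amp_fraction * np.exp(
        -0.5 * ((t - dia_center) / w) ** 2)
    return params.systolic_amp * (sys_lobe + dia_lobe)


def generate_rr(params: PhysioParams,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Beat-interval sequence covering ``duration_s``.

    Intervals are i.i.d. Gaussian around ``60 / mean_hr_bpm`` with SD
    ``sdnn_s``, floored at 0.3 s; generation stops once the cumulative
    onset time reaches the duration.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    mean_rr = 60.0 / params.mean_hr_bpm
    out: list[float] = []
    t = 0.0
    while t < params.duration_s:
        rr = mean_rr + (rng.normal(0.0, params.sdnn_s) if params.sdnn_s else 0.0)
        rr = max(rr, MIN_RR_S)
        out.append(rr)
        t += rr
    return np.asarray(out)


def _artifact_bursts(n: int, fs: float, params: PhysioParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Poisson-arriving motion bursts of band-limited (0.5-10 Hz) noise."""
    x = np.zeros(n)
    if params.artifact_rate_per_min <= 0 or params.artifact_amp <= 0:
        return x
    t0 = min(params.artifact_start_s, params.duration_s)
    active_s = params.duration_s - t0
    n_bursts = rng.poisson(params.artifact_rate_per_min * active_s / 60.0)
    if n_bursts == 0:
        return x
    sos = sps.butter(2, [0.5, 10.0], btype="bandpass", fs=fs, output="sos")
    for _ in range(n_bursts):
        dur = rng.uniform(0.5, 3.0)
        start = int(rng.uniform(t0 * fs, max(t0 * fs + 1, n - dur * fs)))
        length = min(int(dur * fs), n - start)
        burst = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, length + int(2 * fs)))
        burst = burst[int(fs):int(fs) + length]
        scale = burst.std() or 1.0
        x[start:start + length] += params.artifact_amp * burst / scale
    return x


def generate_clean(params: PhysioParams, fs: float = 1000.0,
                   rng: np.random.Generator | None = None
                   ) -> tuple[Signal, GroundTruth]:
    """Render the pulse train in normalized physiological units.

    Beats are concatenated on the :func:`generate_rr` grid; respiratory
    baseline ``resp_amp * sin(2*pi*resp_rate_hz*t)``, white Gaussian noise
    of SD ``noise_sd`` and (optionally) motion-artifact bursts are added.
    Ground-truth systolic peak times sit at each beat's systolic center.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rr = generate_rr(params, rng)
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    onsets = np.concatenate([[0.0], np.cumsum(rr)])
    peak_times = []
    # Lobes are summed on the absolute timeline: widths and the diastolic
    # delay keep their reference-beat durations while the systolic center
    # tracks 0.25 of each actual beat, so high-rate beats overlap smoothly
    # instead of being compressed copies of the template.
    sigma = params.pulse_width_fraction * REF_BEAT_S
    dia_delay = params.diastolic_delay_fraction * REF_BEAT_S
    reach = 5.0 * sigma
    # The overlapping diastolic lobe pulls the waveform maximum slightly
    # past the systolic center; resolve the combined-lobe argmax once on a
    # fine grid so ground-truth peak times sit on the rendered maxima.
    tt = np.linspace(-sigma, sigma, 2001)
    lobe_pair = (np.exp(-0.5 * (tt / sigma) ** 2)
                 + params.diastolic_amp_fraction
                 * np.exp(-0.5 * ((tt - dia_delay) / sigma) ** 2))
    peak_shift = float(tt[np.argmax(lobe_pair)])
    for k, rr_k in enumerate(rr):
        sys_c = onsets[k] + SYSTOLIC_CENTER * rr_k
        for center, amp in ((sys_c, params.systolic_amp),
                            (sys_c + dia_delay,
                             params.systolic_amp * params.diastolic_amp_fraction)):
            i0 = max(0, int(np.floor((center - reach) * fs)))
            i1 = min(n, int(np.ceil((center + reach) * fs)))
            if i0 < i1:
                x[i0:i1] += amp * np.exp(
                    -0.5 * ((t[i0:i1] - center) / sigma) ** 2)
        if sys_c + peak_shift < params.duration_s:
            peak_times.append(sys_c + peak_shift)
    x += params.resp_amp * np.sin(2 * np.pi * params.resp_rate_hz * t)
    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd, n)
    x += _artifact_bursts(n, fs, params, rng)
    sig = Signal(samples=x, fs=fs, sensor_label="physio", site=None,
                 device="synthetic")
    truth = GroundTruth(peak_times_s=np.asarray(peak_times), rr_s=rr)
    return sig, truth


def _soft_knee(v: np.ndarray, knee: float, ceiling: float) -> np.ndarray:
    """Quadratic soft-clip: tangent at the knee, saturating at the ceiling.

    For ``knee <= v <= 2*ceiling - knee`` the response is
    ``v - (v - knee)**2 / (4*(ceiling - knee))``; beyond that it is flat at
    the ceiling.  Monotone non-decreasing everywhere.
    """
    if ceiling <= knee:
        return np.minimum(v, ceiling)
    out = v.astype(float).copy()
    over = v > knee
    vv = np.minimum(v[over], 2 * ceiling - knee)
    out[over] = vv - (vv - knee) ** 2 / (4.0 * (ceiling - knee))
    return out


def apply_front_end(signal: Signal, sensor: SensorConfig,
                    truth: GroundTruth | None = None
                    ) -> tuple[Signal, GroundTruth]:
    """Pass a physiological signal through amplifier + ADC.

    The sample is scaled by ``gain * site_gain``, biased to mid-range,
    soft-compressed above ``ceiling_knee_fraction`` of the ADC range,
    hard-clipped at ``2**bits - 1`` and rounded to an integer code.  The
    saturation mask marks samples whose pre-compression value exceeded the
    knee (compression is strictly increasing below the hard clip, so this
    is exactly the set of samples whose output exceeds the knee).
    """
    x = np.asarray(signal.samples, float)
    ceiling = float(sensor.adc_max)
    offset = 0.5 * ceiling
    linear = sensor.gain * sensor.site_gain * x + offset
    knee = sensor.ceiling_knee_fraction * ceiling
    compressed = _soft_knee(linear, knee, ceiling)
    quantized = np.clip(np.rint(compressed), 0, ceiling).astype(np.int64)
    mask = linear > knee
    out = Signal(samples=quantized, fs=signal.fs, adc_bits=sensor.adc_bits,
                 sensor_label=sensor.label, site=sensor.site,
                 device=sensor.device, t0=signal.t0)
    if truth is None:
        new_truth = GroundTruth(peak_times_s=np.array([]), rr_s=np.array([]))
    else:
        new_truth = replace(truth)
    new_truth.saturated_mask = mask
    new_truth.clip_level = int(ceiling)
    return out, new_truth


def calibration_drive(sensor: SensorConfig, duration_s: float = 10.0,
                      fs: float = 1000.0, seed: int = 0
                      ) -> tuple[Signal, GroundTruth]:
    """Emulate the bench saturation test: LED light aimed straight at the
    photodiode for ``duration_s``, driving the front end deep past its knee.

    The drive level sweeps slowly through the onset of saturation — from
    just below the compression knee to past the hard ceiling — with a
    small noise floor, emulating the iterative bench procedure of backing
    the light level in and out of saturation.  The resulting
    saturated-sample distribution has spread (minimum well below the
    mean) instead of a single hard-clip value, and its mu - 1*sigma
    endpoint lands near the knee where saturation physically begins.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    full_scale = sensor.adc_max / (2.0 * sensor.gain * sensor.site_gain)
    drive = full_scale * (0.97 + 0.24 * np.sin(2 * np.pi * 0.3 * t)
                          + rng.normal(0.0, 0.01, n))
    sig = Signal(samples=drive, fs=fs, sensor_label=sensor.label,
                 site=sensor.site, device=sensor.device)
    return apply_front_end(sig, sensor, None)


@dataclass
class DualDeviceResult:
    """Two single-device recordings of the same physiology plus truth."""

    recording_a: Recording
    recording_b: Recording
    truth_a: GroundTruth
    truth_b: GroundTruth
    offset_samples: int


def _sync_channel(n: int, fs: float, pulse_time_s: float,
                  pulse_dur_s: float = 0.1, height: float = 1.0) -> Signal:
    x = np.zeros(n)
    i0 = int(round(pulse_time_s * fs))
    i1 = min(int(round((pulse_time_s + pulse_dur_s) * fs)), n)
    x[i0:i1] = height
    return Signal(samples=x, fs=fs, sensor_label="sync")


def generate_dual_device(params: PhysioParams,
                         sensors: tuple[SensorConfig, SensorConfig] |
                                  dict[str, SensorConfig],
                         offset_samples: int = 0,
                         fs: float = 1000.0,
                         seed: int | None = None,
                         sync_time_s: float = 0.5) -> DualDeviceResult:
    """Render one physiology through two device front ends.

    Device B starts recording ``offset_samples`` samples before device A
    (negative values: after), so every shared physiological instant —
    including the 100 ms optical sync pulse fired at ``sync_time_s`` —
    appears ``offset_samples`` later in B's timebase.  The sensors argument
    is either a pair or a ``{channel_name: SensorConfig}`` mapping split
    between the devices (first half on A, rest on B).
    """
    if seed is not None:
        params = replace(params, seed=seed)
    if isinstance(sensors, dict):
        names = list(sensors)
        half = max(1, len(names) // 2)
        dev_a = {k: sensors[k] for k in names[:half]}
        dev_b = {k: sensors[k] for k in names[half:]}
    elif isinstance(sensors[0], dict):
        dev_a, dev_b = sensors
    else:
        dev_a = {sensors[0].label: sensors[0]}
        dev_b = {sensors[1].label: sensors[1]}

    # Render one "world" physiology long enough for both shifted views.
    # Device D records world samples [s_D, s_D + n); a shared world instant
    # w appears at index w - s_D, so choosing s_A - s_B = offset_samples
    # makes every shared event (sync pulse included) occur offset_samples
    # later in B's timebase than in A's.
    pad = abs(int(offset_samples))
    phys_params = replace(params, duration_s=params.duration_s + pad / fs)
    physio, truth = generate_clean(phys_params, fs)
    n = int(round(params.duration_s * fs))
    s_a = max(0, int(offset_samples))
    s_b = max(0, -int(offset_samples))
    w_sync = pad / fs + sync_time_s

    def build(start: int, configs: dict[str, SensorConfig]
              ) -> tuple[Recording, GroundTruth]:
        base = Signal(samples=physio.samples[start:start + n], fs=fs)
        pt = truth.peak_times_s - start / fs
        pt = pt[(pt >= 0) & (pt < n / fs)]
        gt = GroundTruth(peak_times_s=pt, rr_s=truth.rr_s)
        chans: dict[str, Signal] = {}
        for name, cfg in configs.items():
            chans[name], gt = apply_front_end(base, cfg, gt)
        aux = _sync_channel(n, fs, w_sync - start / fs)
        return Recording(signals=chans, aux_sync=aux), gt

    rec_a, gt_a = build(s_a, dev_a)
    rec_b, gt_b = build(s_b, dev_b)
    return DualDeviceResult(rec_a, rec_b, gt_a, gt_b, int(offset_samples))
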