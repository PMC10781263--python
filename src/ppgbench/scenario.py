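"""End-to-end benchmark scenario: simulate, align, calibrate, score, report.

A scenario describes a two-device synthetic acquisition (physiology,
per-channel sensor front ends, inter-device clock offset) and the analysis
settings.  Running it executes the full pipeline — simulation, optical
re-synchronization, saturation calibration and classification,
spectral-entropy quality, systolic-peak detection, morphology against the
reference channel, and heart-rate evaluation against generator ground
truth — and emits one machine-readable table with a row per sensor and
segment label, mirroring how multi-sensor PPG benchmarks are tabulated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, morphology, saturation
from .detection import ElgendiParams, FilterSpec, PeakSet, detect_peaks
from .quality import InsufficientDataError, QualitySpec, quality_profile
from .signal_io import (Recording, Signal, SyncResult, align_recordings,
                        label_segments, write_signal)
from .synth import (DualDeviceResult, PhysioParams, SensorConfig,
                    calibration_drive, generate_dual_device)

log = logging.getLogger("ppgbench")

__all__ = ["Scenario", "ScenarioResult", "default_scenario", "load_scenario",
           "run_scenario"]


@dataclass
class Scenario:
    """Configuration of one end-to-end benchmark run."""

    physio: PhysioParams
    sensors_a: dict[str, SensorConfig]
    sensors_b: dict[str, SensorConfig]
    reference_channel: str
    offset_samples: int = 0
    fs: float = 1000.0
    rest_duration_s: float = 120.0
    initial_threshold_fraction: float = 0.8
    quality: QualitySpec = field(default_factory=QualitySpec)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    elgendi: ElgendiParams = field(default_factory=ElgendiParams)
    match_tolerance_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        channels = {**self.sensors_a, **self.sensors_b}
        if self.reference_channel not in channels:
            raise ValueError(
                f"reference channel {self.reference_channel!r} not among "
                f"channels {sorted(channels)}"
            )


@dataclass
class ScenarioResult:
    """Everything one scenario run produced."""

    report: pd.DataFrame
    sync: SyncResult
    simulated: DualDeviceResult
    aligned: Recording
    truth_peaks: PeakSet
    profiles: dict[str, saturation.SaturationProfile]


def default_scenario(seed: int = 0, duration_s: float = 240.0,
                     rest_duration_s: float = 120.0,
                     offset_samples: int = 137) -> Scenario:
    """The bundled two-device, four-sensor study configuration.

    Device A carries two 10-bit finger sensors (low-gain and stock-gain,
    the latter saturating on systolic peaks); device B carries two 23-bit
    high-gain sensors at damped sites (arm, ankle).  Motion artifacts
    start after the at-rest period.
    """
    physio = PhysioParams(
        mean_hr_bpm=70.0, duration_s=duration_s, seed=seed,
        artifact_rate_per_min=6.0, artifact_amp=0.6,
        artifact_start_s=rest_duration_s,
    )
    sensors_a = {
        "G_lowMidBit": SensorConfig(r6_ohm=1e6, adc_bits=10, site_gain=2.0,
                                    label="G_low", site="middle finger",
                                    device="A"),
        "G_defIndBit": SensorConfig(r6_ohm=3.3e6, adc_bits=10, site_gain=2.0,
                                    label="G_def", site="index finger",
                                    device="A"),
    }
    sensors_b = {
        "G_highArmSci": SensorConfig(r6_ohm=1e7, adc_bits=23, site_gain=0.5,
                                     label="G_high", site="upper arm",
                                     device="B"),
        "G_highAnkSci": SensorConfig(r6_ohm=1e7, adc_bits=23, site_gain=0.3,
                                     label="G_high", site="ankle",
                                     device="B"),
    }
    return Scenario(physio=physio, sensors_a=sensors_a, sensors_b=sensors_b,
                    reference_channel="G_lowMidBit",
                    offset_samples=offset_samples,
                    rest_duration_s=rest_duration_s, seed=seed)


def _sensor_from_table(tbl: dict) -> SensorConfig:
    fields = {f.name for f in dataclasses.fields(SensorConfig)}
    return SensorConfig(**{k: v for k, v in tbl.items() if k in fields})


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from TOML.

    Tables: ``[physio]`` (PhysioParams fields), ``[sensor.<name>]``
    (SensorConfig fields plus ``device = "A"|"B"``), ``[sync]``
    (``offset_samples``), ``[run]`` (reference_channel, rest_duration_s,
    seed, fs, match_tolerance_s).
    """
    cfg = tomllib.loads(Path(path).read_text())
    physio_fields = {f.name for f in dataclasses.fields(PhysioParams)}
    physio = PhysioParams(**{k: v for k, v in cfg.get("physio", {}).items()
                             if k in physio_fields})
    sensors_a: dict[str, SensorConfig] = {}
    sensors_b: dict[str, SensorConfig] = {}
    for name, tbl in cfg.get("sensor", {}).items():
        target = sensors_b if tbl.get("device", "A").upper() == "B" else sensors_a
        target[name] = _sensor_from_table(tbl)
    run = cfg.get("run", {})
    return Scenario(
        physio=physio, sensors_a=sensors_a, sensors_b=sensors_b,
        reference_channel=run.get("reference_channel",
                                  next(iter(sensors_a), "")),
        offset_samples=int(cfg.get("sync", {}).get("offset_samples", 0)),
        fs=float(run.get("fs", 1000.0)),
        rest_duration_s=float(run.get("rest_duration_s", 120.0)),
        seed=int(run.get("seed", physio.seed)),
        match_tolerance_s=float(run.get("match_tolerance_s", 0.05)),
    )


def _align_channels(sim: DualDeviceResult, sync: SyncResult) -> Recording:
    """Merge both devices' channels onto device A's timebase.

    Device B's samples are shifted by the recovered offset and every
    channel is cropped to the common support.
    """
    off = sync.offset_samples
    n = min(len(s) for r in (sim.recording_a, sim.recording_b)
            for s in r.signals.values())
    common = n - abs(off)
    signals: dict[str, Signal] = {}
    for name, sig in sim.recording_a.signals.items():
        sl = slice(0, common) if off >= 0 else slice(-off, -off + common)
        signals[name] = replace(sig, samples=sig.samples[sl])
    for name, sig in sim.recording_b.signals.items():
        sl = slice(off, off + common) if off >= 0 else slice(0, common)
        signals[name] = replace(sig, samples=sig.samples[sl])
    return Recording(signals=signals, aux_sync=sim.recording_a.aux_sync)


def _segment_row(name: str, label: str, seg: slice, signal: Signal,
                 sat_report: saturation.SaturationReport,
                 truth_seg: PeakSet, reference: Signal | None,
                 sc: Scenario) -> dict:
    """All metrics for one channel within one labeled segment."""
    row: dict = {"sensor": name, "segment": label}
    flags: list[str] = []
    fs = signal.fs
    seg_sig = replace(signal, samples=signal.samples[seg], adc_bits=None)
    mask = sat_report.mask[seg]
    row["pct_saturated"] = 100.0 * float(mask.mean())

    seg_report = saturation.SaturationReport(
        percent_saturated=row["pct_saturated"], mask=mask,
        runs=saturation._runs_from_mask(mask))
    try:
        qr = quality_profile(seg_sig, sc.quality)
        row["mean_se"] = qr.mean_se
        excl = saturation.remove_saturated_windows(seg_sig, seg_report,
                                                   sc.quality.window_s)
        try:
            qr_ns = quality_profile(seg_sig, sc.quality, exclusion_mask=excl)
            row["mean_se_no_sat"] = qr_ns.mean_se_excluding_saturated
        except InsufficientDataError:
            flags.append("quality:every window saturated")
    except InsufficientDataError as exc:
        flags.append(f"quality:{exc}")

    try:
        peaks, filtered = detect_peaks(seg_sig, sc.filter_spec, sc.elgendi)
        match = evaluation.match_peaks(truth_seg, peaks, sc.match_tolerance_s)
        row["sensitivity"] = match.sensitivity
        row["precision"] = match.precision
        if len(peaks) >= 2 and len(truth_seg) >= 2:
            auto_hr = evaluation.hr_from_peaks(peaks)
            truth_hr = evaluation.hr_from_peaks(truth_seg)
            diff, pct = evaluation.hr_error(auto_hr, truth_hr)
            row["hr_diff_bpm"] = diff
            row["pct_error"] = pct
        if reference is not None:
            ref_seg = replace(reference, samples=reference.samples[seg],
                              adc_bits=None)
            ref_pk, ref_filt = detect_peaks(ref_seg, sc.filter_spec,
                                            sc.elgendi)
            if len(ref_pk) >= 3 and len(peaks) >= 3:
                morph = morphology.compare_pulses(
                    filtered, peaks, ref_filt, ref_pk,
                    quality_spec=sc.quality)
                row["pcc"] = morph.pcc
                row["cs"] = morph.cs
                row["ned"] = morph.ned
            else:
                flags.append("morphology:too-few-peaks")
    except Exception as exc:  # continue per-channel with failure flags
        flags.append(f"detection:{exc}")
        log.warning("channel %s segment %s: %s", name, label, exc)
    row["error_flag"] = ";".join(flags) if flags else None
    return row


def run_scenario(sc: Scenario, out_dir: str | Path | None = None
                 ) -> ScenarioResult:
    """Execute the full pipeline for one scenario.

    Deterministic given ``sc.seed``.  When ``out_dir`` is given, writes
    ``report.csv``, ``sync.json``, ``saturation_profiles.json`` and the
    simulated channel CSVs there.
    """
    log.info("simulating %d-channel dual-device scenario, seed %d",
             len(sc.sensors_a) + len(sc.sensors_b), sc.seed)
    sim = generate_dual_device(sc.physio, (sc.sensors_a, sc.sensors_b),
                               offset_samples=sc.offset_samples, fs=sc.fs,
                               seed=sc.seed)
    sync = align_recordings(sim.recording_a, sim.recording_b)
    log.info("optical sync: offset %d samples", sync.offset_samples)
    aligned = _align_channels(sim, sync)
    aligned = label_segments(aligned, sc.rest_duration_s)

    truth = PeakSet.from_times(sim.truth_a.peak_times_s, sc.fs)
    configs = {**sc.sensors_a, **sc.sensors_b}

    profiles: dict[str, saturation.SaturationProfile] = {}
    reports: dict[str, saturation.SaturationReport] = {}
    for name, cfg in configs.items():
        cal, _ = calibration_drive(cfg, fs=sc.fs, seed=sc.seed + 1)
        profiles[name] = saturation.calibrate_threshold(
            cal, sc.initial_threshold_fraction * cfg.adc_max)
        reports[name] = saturation.classify_saturation(
            aligned.signals[name], profiles[name])

    ref_name = sc.reference_channel
    rows = []
    for start_s, end_s, label in aligned.labels:
        seg = slice(int(round(start_s * sc.fs)), int(round(end_s * sc.fs)))
        t_in = (truth.times_s >= start_s) & (truth.times_s < end_s)
        truth_seg = PeakSet.from_times(truth.times_s[t_in] - start_s, sc.fs)
        for name in configs:
            reference = aligned.signals[ref_name] if name != ref_name else None
            rows.append(_segment_row(
                name, label, seg, aligned.signals[name], reports[name],
                truth_seg, reference, sc))
    report = evaluation.benchmark_report(rows)

    result = ScenarioResult(report=report, sync=sync, simulated=sim,
                            aligned=aligned, truth_peaks=truth,
                            profiles=profiles)
    if out_dir is not None:
        _write_artifacts(result, sc, Path(out_dir))
    return result


def _write_artifacts(res: ScenarioResult, sc: Scenario, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    res.report.to_csv(out / "report.csv", index=False)
    (out / "sync.json").write_text(json.dumps({
        "offset_samples": res.sync.offset_samples,
        "edge_a_s": res.sync.edge_a_s,
        "edge_b_s": res.sync.edge_b_s,
    }, indent=1))
    (out / "saturation_profiles.json").write_text(json.dumps({
        name: dataclasses.asdict(prof)
        for name, prof in res.profiles.items()
    }, indent=1))
    (out / "ground_truth_peaks.json").write_text(json.dumps({
        "fs": sc.fs,
        "indices": res.truth_peaks.indices.tolist(),
        "provenance": res.truth_peaks.provenance,
    }))
    for name, sig in res.aligned.signals.items():
        write_signal(sig, out / f"{name}.csv")
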