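#!/usr/bin/env python
"""Systolic-peak detection accuracy and heart-rate error.

Two experiments.  (1) The simulated study: per sensor and segment,
sensitivity/precision of the two-moving-average detector against
generator ground truth at ±50 ms, plus absolute mean-HR difference and
percent error (5% is the conventional clinical acceptability bound) and
Poincaré SD1/SD2 of the detected beat intervals.  (2) A heart-rate sweep
on clean 120 s signals showing the detector's operating range with the
study's parameters (peak window 0.18 s, beat window 0.69 s): recovery is
essentially perfect at 60-120 BPM and degrades at both extremes — at
150 BPM candidate blocks shrink below the 0.18 s width rule, at 50 BPM
the sub-passband fundamental causes one filter-rebound false positive
per beat.
"""

import sys
from pathlib import Path

import pandas as pd

from ppgbench import (PeakSet, PhysioParams, detect_peaks, generate_clean,
                      match_peaks, poincare)
from ppgbench.scenario import default_scenario, run_scenario

ROOT = Path(__file__).resolve().parents[1]


def study_table(seed: int) -> pd.DataFrame:
    res = run_scenario(default_scenario(seed=seed))
    cols = ["sensor", "segment", "sensitivity", "precision",
            "hr_diff_bpm", "pct_error"]
    df = res.report[cols].copy()
    df["hr_acceptable"] = df.pct_error < 5.0
    # Poincaré descriptors of the detected beats, whole recording
    sd1, sd2 = {}, {}
    for name, sig in res.aligned.signals.items():
        peaks, _ = detect_peaks(sig)
        desc = poincare(peaks)
        sd1[name], sd2[name] = desc.sd1_ms, desc.sd2_ms
    df["sd1_ms"] = df.sensor.map(sd1)
    df["sd2_ms"] = df.sensor.map(sd2)
    return df


def hr_sweep(seed: int) -> pd.DataFrame:
    rows = []
    for hr in (50, 60, 70, 90, 120, 150):
        params = PhysioParams(mean_hr_bpm=float(hr), duration_s=120.0,
                              seed=seed + hr)
        sig, truth = generate_clean(params, 1000.0)
        peaks, _ = detect_peaks(sig)
        m = match_peaks(PeakSet.from_times(truth.peak_times_s, 1000.0), peaks)
        rows.append({"mean_hr_bpm": hr, "n_true_beats": len(truth.peak_times_s),
                     "sensitivity": m.sensitivity, "precision": m.precision})
    return pd.DataFrame(rows)


def main(seed: int = 0) -> None:
    (ROOT / "results").mkdir(exist_ok=True)
    study = study_table(seed)
    study.to_csv(ROOT / "results" / "detection_hr.csv", index=False)
    print("study channels (vs generator ground truth, ±50 ms):")
    print(study.round(3).to_string(index=False))

    sweep = hr_sweep(seed)
    sweep.to_csv(ROOT / "results" / "detector_hr_sweep.csv", index=False)
    print("\ndetector operating range on clean signals:")
    print(sweep.round(3).to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
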