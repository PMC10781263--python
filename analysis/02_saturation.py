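#!/usr/bin/env python
"""Calibrate saturation thresholds and quantify per-channel saturation.

For each sensor front end, a 10 s driven-saturation run (light aimed
straight at the photodiode, swept through the onset of saturation) is
processed with the mu - 1*sigma rule: the final threshold is the mean of
the samples above the manual initial threshold minus one population SD.
The calibrated thresholds are then applied to the simulated study
channels.  Expected pattern: the stock-gain finger sensor saturates on
systolic peaks (~20% of samples); the low-gain finger and the damped
arm/ankle sensors barely saturate at all.
"""

import sys
from pathlib import Path

import pandas as pd

from ppgbench import calibrate_threshold, calibration_drive, classify_saturation
from ppgbench.scenario import default_scenario, run_scenario

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    sc = default_scenario(seed=seed)
    res = run_scenario(sc)

    cal_rows, sig_rows = [], []
    for name, cfg in {**sc.sensors_a, **sc.sensors_b}.items():
        cal, _ = calibration_drive(cfg, fs=sc.fs, seed=seed + 1)
        prof = calibrate_threshold(cal,
                                   sc.initial_threshold_fraction * cfg.adc_max)
        cal_rows.append({
            "channel": name, "adc_bits": cfg.adc_bits,
            "min": prof.min_above, "max": prof.max_above,
            "median": prof.median_above, "mean": prof.mean_above,
            "sd": prof.sd_above, "final_threshold": prof.final_threshold,
            "n_samples": prof.n_samples_above,
        })
        rep = classify_saturation(res.aligned.signals[name], prof)
        sig_rows.append({"channel": name,
                         "pct_saturated": rep.percent_saturated,
                         "n_saturated_runs": len(rep.runs)})

    cal_df = pd.DataFrame(cal_rows)
    sig_df = pd.DataFrame(sig_rows)
    (ROOT / "results").mkdir(exist_ok=True)
    cal_df.to_csv(ROOT / "results" / "saturation_calibration.csv", index=False)
    sig_df.to_csv(ROOT / "results" / "saturation_percent.csv", index=False)
    print("calibration statistics (samples above the initial threshold):")
    print(cal_df.round(1).to_string(index=False))
    print("\nper-channel saturation under the calibrated thresholds:")
    print(sig_df.round(3).to_string(index=False))
    print("\nnote the spread (min << mean): saturation onset is gradual, "
          "which is why a statistical threshold beats a manual one.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
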