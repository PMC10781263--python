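# ppgbench

Benchmarking pipeline for photoplethysmography (PPG) sensor
configurations: saturation-threshold calibration, spectral-entropy signal
quality, systolic-peak detection, pulse-morphology comparison and
heart-rate accuracy — plus a synthetic two-device acquisition model with
exact ground truth so the whole chain is verifiable without human
recordings.

Low-cost analog PPG sensors are routinely re-tuned by swapping the
feedback resistor of their transimpedance amplification stage
(`Av = 1 + R6/R5`; the stock 3.3 MΩ / 10 kΩ pair gives a gain of 331).
Too much gain drives the signal into the ADC ceiling and flattens the
systolic peaks; too little buries weak sites in quantization noise.  This
package implements the measurements used to compare such configurations
across anatomical sites and acquisition devices:

- **Saturation (μ−1σ rule)** — from a driven calibration run, the final
  saturation threshold is the mean of the samples above a manual initial
  threshold minus one standard deviation; signals are scored by the
  percentage of samples at or above it.
- **Spectral entropy (SE)** — Shannon entropy of the normalized 1–3 Hz
  power spectrum per consecutive 4 s window, scaled to [0, 1]; periodic
  pulses score low, noise scores high, and a mean SE above 0.8 flags poor
  quality.
- **Peak detection** — 4th-order Butterworth bandpass [1, 8] Hz, then the
  two-event-related-moving-average detector (peak window 0.18 s, beat
  window 0.69 s, offset 0.01), evaluated against ground truth by
  sensitivity and precision at ±50 ms.
- **Morphology** — one beat per channel pair, min-max normalized,
  lag-realigned, scored by Pearson correlation (PCC), cosine similarity
  (CS) and Euclidean distance of the normalized pulses (nED).
- **Heart rate** — instantaneous HR = 60/IBI from inter-peak intervals;
  absolute mean-HR difference and percent error versus ground truth;
  Poincaré SD1/SD2 of the beat intervals.
- **Synchronization** — two devices are aligned by a shared optical pulse
  (LED on one device, light sensor on the other), recovering the
  inter-device clock offset to one sample.

See `docs/methods.md` for the model and every numerical choice.

## Worked example

Run the bundled two-device scenario (240 s of 70 BPM physiology, four
sensors, motion artifacts after the first 120 s, a 137-sample clock
offset between devices):

```python
from ppgbench.scenario import default_scenario, run_scenario

res = run_scenario(default_scenario(seed=0))
print(res.sync.offset_samples)
cols = ["sensor", "segment", "pct_saturated", "mean_se",
        "sensitivity", "precision", "pct_error", "pcc"]
print(res.report[cols].round(3).to_string(index=False))
```

```
137
      sensor  segment  pct_saturated  mean_se  sensitivity  precision  pct_error   pcc
 G_lowMidBit  at_rest          0.000    0.625        1.000      1.000      0.006   NaN
 G_defIndBit  at_rest         22.347    0.582        0.993      0.993      0.091 0.980
G_highArmSci  at_rest          0.000    0.625        1.000      1.000      0.006 1.000
G_highAnkSci  at_rest          0.000    0.625        1.000      1.000      0.006 1.000
 G_lowMidBit movement          0.132    0.721        0.864      0.852      3.651   NaN
 G_defIndBit movement         24.585    0.685        0.879      0.848     10.257 0.984
G_highArmSci movement          0.000    0.721        0.864      0.852      3.652 1.000
G_highAnkSci movement          0.000    0.721        0.864      0.852      3.651 1.000
```

Reading the table: the optical sync recovered the injected 137-sample
offset exactly.  The stock-gain finger sensor (`G_defIndBit`, gain 331)
saturates on 22% of its at-rest samples and — counter-intuitively —
shows the *lowest* spectral entropy, because flat-topped pulses
concentrate spectral power at the cardiac line; its pulse shape also
correlates least with the low-gain reference (PCC 0.980 vs 1.000).
Movement artifacts raise entropy on every channel, degrade detection to
~0.86/0.85, and push the saturating channel's heart-rate error past the
5% clinical acceptability bound.  `pcc` is NaN for the reference channel
itself.

The same pipeline is available stepwise as numbered drivers
(`analysis/01_simulate.py` … `05_morphology.py`, each writing a table
under `results/`) and as a CLI:

```sh
ppgbench simulate --seed 0 --out sim/
ppgbench align --a sim/sync_A.csv --b sim/sync_B.csv --out offsets.json
ppgbench detect --in sim/G_lowMidBit.csv --out peaks.json
ppgbench report --seed 0 --out report.csv
```

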