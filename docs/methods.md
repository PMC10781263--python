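# Methods

## Scope

`ppgbench` benchmarks photoplethysmography (PPG) sensor configurations the
way a multi-sensor acquisition study is analyzed: calibrate a saturation
threshold per sensor, score signal quality by spectral entropy, detect
systolic peaks with a two-moving-average detector, compare pulse
morphology between simultaneously recorded channels, and report
heart-rate accuracy against ground truth — stratified into at-rest and
movement segments.  Because such studies rarely deposit raw recordings,
the package ships a synthetic acquisition model with exact ground truth
(peak times, beat intervals, per-sample saturation) so every stage is
verifiable end to end.

## Synthetic acquisition model

**Pulse train.**  Each beat contributes two Gaussian lobes: a systolic
lobe (amplitude 1 by default) whose center sits at 0.25 of the actual
beat interval, and a diastolic lobe (relative amplitude 0.35) delayed by
0.18 s.  Lobe width (sigma 0.08 s) and the diastolic delay are anchored
in absolute time rather than scaled per beat, because systolic ejection
shortens far less than the beat interval as heart rate rises; lobes are
summed on the absolute timeline so overlapping beats at high rates merge
smoothly.  The 0.18 s / 0.08 s pairing (2.25 sigma separation) renders
the diastolic wave as a dicrotic shoulder on the systolic decay, as in
real pulses, rather than a detached second pulse.  Ground-truth peak
times are the argmax of the combined lobe pair, resolved once on a
0.1 ms grid: the diastolic overlap pulls the true maximum ~6 ms past the
systolic center, and the ground truth must sit on the rendered maxima
for millisecond-level detector scoring to be meaningful.

**Beat intervals** are i.i.d. Gaussian around 60/HR with SD `sdnn_s`
(default 30 ms, a typical short-term resting variability), floored at
0.3 s.  No autoregressive structure is modeled; Poincaré SD1 therefore
equals the interval SD in expectation, which the tests exploit as a
closed form.

**Disturbances.**  Respiratory baseline wander is a 0.25 Hz sinusoid
(amplitude 5% of the systolic amplitude), additive white noise has SD 1%
by default, and motion artifacts are Poisson-arriving bursts (0.5–3 s)
of 0.5–10 Hz band-limited noise that can be gated to start after the
at-rest period, emulating a rest-then-task protocol.

**Front end.**  The transimpedance amplification stage has closed-loop
gain `Av = 1 + R6/R5`; the stock 3.3 MΩ / 10 kΩ pair gives 331, and the
simulated sensor variants differ only in R6 (1 MΩ → 101, 10 MΩ → 1001)
and in a site-dependent amplitude factor (finger 2.0 > toe 1.5 > wrist
0.8 > arm 0.5 > ankle 0.3, qualitatively matching perfusion differences
between sites).  The amplified signal is biased to mid-range (half the
ADC span, emulating the sensor's biased analog output), soft-compressed
above a knee at 0.9 of the ADC span, hard-clipped at `2^bits − 1` and
rounded to integer codes (10-bit and 23-bit converters by default).  The
soft knee is a quadratic blend — tangent at the knee, flat at the
ceiling — so saturation is gradual: the saturated-sample distribution
has genuine spread (minimum well below the mean), which is what makes a
statistical threshold preferable to a manual one.  The ground-truth
saturation mask marks samples whose pre-compression value exceeds the
knee; compression is strictly increasing below the hard clip, so this
equals the set of output samples above the knee.

**Two devices.**  Both devices view one "world" physiology; device B's
sample window is shifted by the configured offset, so every shared event
— including a 100 ms optical sync pulse — appears that many samples
later in B's timebase.  Alignment recovers the offset as
`round((edge_b − edge_a) · fs)` from the first 50% rising crossing of
each sync channel; sub-sample interpolation is deliberately omitted
(1 sample at 1 kHz is negligible against the 50 ms matching tolerance).

**Calibration drive.**  The driven-saturation bench test is emulated as
a light level swept slowly (0.3 Hz) through the onset of saturation,
from just below the compression knee to past the ceiling, with a 1%
noise floor.  The sweep is chosen so the μ−1σ endpoint of the
above-threshold samples lands at the knee — the operating point the
iterative bench procedure converges to — which makes the calibrated
threshold agree with the ground-truth saturation mask on >99% of
samples in the bundled scenario.

## Analysis pipeline

**Saturation (μ−1σ rule).**  Statistics are computed over calibration
samples strictly above the manual initial threshold (default 0.8 of the
ADC span); the final threshold is the mean minus one *population* SD
(ddof=0 — the deterministic reading of "one standard deviation";
configurable).  Classification is inclusive (`≥ threshold`): the
threshold is itself a saturation value.  Only ceiling saturation is
modeled.  For saturation-free quality scoring, whole analysis windows
containing any saturated sample are excluded rather than splicing
samples out, which would create discontinuities.

**Spectral entropy.**  Per consecutive, non-overlapping 4 s window, the
power spectral density is estimated by Welch averaging of 2 s
rectangular segments with 75% overlap (five 0.5 Hz bins in the 1–3 Hz
band, mean removed per segment); in-band bins are renormalized to sum to
one and the Shannon entropy is divided by log2 of the bin count, giving
SE ∈ [0, 1].  Band edges are inclusive.  Windows with zero in-band power
are flagged undefined and excluded from means.  A raw single-window
periodogram was rejected: its per-bin chi-squared fluctuations bias the
entropy of white noise to ≈0.83 (for nine bins, E[SE] = (H₉−1)/ln 2 /
log₂ 9), breaking the estimator's defining contrast — periodic ≈ low,
noise ≈ 1.  With the averaged estimator, clean synthetic PPG scores
0.62–0.72, a pure in-band tone ≈0, 120 s of white noise ≈0.905, and a
signal is flagged poor quality when its mean SE strictly exceeds 0.8.
Hard-clipped (saturated) signals score *lower* than their clean twins —
flat tops concentrate in-band power at the cardiac line — so low SE
alone must not be read as good quality; the saturation-excluded mean
exists precisely to expose this.

**Detection.**  Signals are bandpass filtered (4th-order Butterworth,
[1, 8] Hz) forward-backward, so peak positions are not phase-shifted
(this doubles the effective order; single-pass filtering is available
but shifts peaks by tens of ms).  The detector is the
two-event-related-moving-average scheme: half-wave rectify, square,
compare a centered 0.18 s moving average against a 0.69 s one plus
0.01 × the mean squared signal, take maximal runs where the short
average wins, discard runs narrower than 0.18 s, and emit the filtered
signal's argmax per surviving run.  Moving-average windows are forced
odd for exact centering; edges are reflect-padded.  The threshold's mean
term is computed per analyzed segment, so statistics never leak across
segment labels.  Onsets (pulse feet) are the minima between consecutive
peaks (the first searched 0.69 s back).

Operating range with these fixed parameters, measured on clean synthetic
signals (see `analysis/04_detection_hr.py`): recovery is ≥0.99 in both
sensitivity and precision for 60–120 BPM, but degrades structurally at
both extremes.  At 150 BPM the candidate-block width becomes marginal
against the 0.18 s width rule (the short average exceeds the long one
for roughly half of the 0.4 s beat), so realistic beat jitter pushes
~1/3 of blocks under the cutoff; at 50 BPM the 0.83 Hz fundamental falls
below the 1 Hz filter edge and the resulting ringing rebound in
mid-diastole fires exactly one false positive per beat.  These are
properties of the parameter set, not defects of the implementation
(which is equivalence-tested against a pointwise brute-force reference);
practitioners targeting bradycardic or exercise recordings should widen
the filter band downward or shorten the peak window.

**Morphology.**  One beat is cut onset-to-onset from each channel,
min-max normalized to [0, 1], resampled to the shorter length by linear
interpolation, then re-synchronized by the lag (±0.25 s) maximizing the
Pearson correlation of the overlapping parts (mean removed per overlap;
normalizing per overlap removes the zero-lag bias of raw
cross-correlation; ties break toward zero lag).  The aligned pair is
scored with PCC, cosine similarity and the Euclidean distance between
the normalized pulses.  Normalization leaves PCC unchanged and is
applied uniformly so one prepared pair feeds all three metrics; the
Euclidean distance is deliberately not divided by length, so its
magnitude grows as √n and only equal-length pulses are comparable.  By
default the compared beat is the one whose containing 4 s windows have
the lowest combined spectral entropy in both channels (best periodic
quality); an explicit beat index overrides this.

**Evaluation.**  Matching is one-to-one greedy in increasing truth-time
order with an inclusive ±50 ms tolerance — the strict reading that never
double-counts a detection.  Sensitivity = TP/(TP+FN), precision =
TP/(TP+FP); precision with zero detections is reported as missing (NaN)
and flagged, not as 0.  Instantaneous HR is 60/IBI; the HR error is the
absolute difference of mean HRs and its percentage of the ground-truth
mean (reported values are magnitudes; 5% is used as the clinical
acceptability flag).  Poincaré SD1/SD2 are the population SDs of the
rotated successive-interval coordinates, in ms.

## Bundled scenario and problem sizes

The default scenario runs 240 s of 70 BPM physiology (120 s at rest,
then motion artifacts at 6 bursts/min) through four sensors — low-gain
and stock-gain 10-bit finger channels on device A; high-gain 23-bit arm
and ankle channels on device B — with a 137-sample inter-device offset.
At these sizes the full pipeline completes in ~1.5 s and the entire test
suite in well under a minute, while every effect of interest (heavy
systolic saturation on the stock gain, near-zero saturation elsewhere,
entropy rise under movement, the reduced-entropy saturation anomaly,
morphology degradation of the clipped channel) is present with wide
margins.

## Known limitations

- The two-Gaussian template has no site-dependent waveform shape — sites
  differ only by amplitude — so cross-site morphology similarity is
  higher than between real anatomical sites; only the saturation-driven
  degradation direction is meaningful.
- At beat intervals much longer than the pulse complex (~0.6 s) the
  template's inter-beat baseline is flat, unlike the exponential
  diastolic runoff of real pulses; this exaggerates filter ringing at
  very low heart rates.
- Intervals are i.i.d.; no respiratory sinus arrhythmia or long-range
  correlation, so SD2 carries no independent information.
- Floor (zero-code) saturation, ringing-artifact repair and artifact
  removal are out of scope; passing tests demonstrate correctness of
  the pipeline on signals obeying this model, not performance on any
  particular human cohort.
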