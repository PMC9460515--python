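# Methods

This note records the models implemented in `tremorsim`, the conventions
and numerical choices behind them, and what the synthetic data does and
does not emulate.

## Sensor error model

An ideal 9-axis record (accelerometer in g, gyroscope in deg/s,
magnetometer in uT) is perturbed per instrument in a fixed order that
mimics a physical signal chain, with digitization last:

1. **Axis misalignment** — a near-identity 3x3 mixing matrix, built from
   three small cross-coupling angles per instrument
   (`misalignment_from_angles`). Validation rejects matrices further than
   0.05 (Frobenius) from identity. Default: identity.
2. **Temperature scale factor** — multiplication by
   `1 + temp_scale_coeff * temp_offset`. Default: off.
3. **Bias** — constant per-axis bias plus a thermal term
   `temp_bias_coeff * temp_offset`. Default: zero.
4. **Stochastic noise**, three processes per axis:
   * *white*: i.i.d. Gaussian with per-sample sigma
     `density * sqrt(fs/2)` — the density is referred to the Nyquist
     bandwidth of the rate at which noise is synthesized;
   * *random walk*: cumulative sum of Gaussian steps with step sigma
     `coeff / sqrt(fs)`, so drift sigma grows as `coeff * sqrt(t)`;
   * *bias instability*: first-order Gauss–Markov process with stationary
     sigma equal to the coefficient and correlation time 100 s (default).
     This is a deliberate stand-in for pink/flicker noise: it reproduces
     the bounded low-frequency wander that matters at trial time scales
     (60 s) without exact 1/f synthesis.
5. **Rate conversion** — zero-phase FIR anti-alias low-pass with cutoff
   `0.45 * target_rate`, then integer decimation (`resample_poly` for
   non-integer ratios). DC is preserved; upsampling is unsupported.
6. **Saturation + quantization** — mid-tread uniform quantizer with
   `LSB = 2 * full_scale / 2**bits`, rounding half away from zero, codes
   clipped to the two's-complement range
   `[-2**(bits-1), 2**(bits-1) - 1]`.

The magnetometer passes only through steps 5–6: the classification study
never uses magnetic data, so no error model is fitted to it.

Shipped presets: `sbg` (1000 Hz, 16 bit, ±16 g, ±1000 deg/s, 57 µg/√Hz,
0.0025 deg/s/√Hz — the reference-grade device), `mmr` (100 Hz, 16 bit,
±16 g, ±2000 deg/s, 180 µg/√Hz, 0.0070 deg/s/√Hz — the wearable),
`mmr_8bit` (8-bit ADC, otherwise `mmr`), and `mmr_8bit_noisy` (8-bit ADC
and all noise densities x 1.10). Presets enable white noise, bias and
quantization; misalignment and temperature terms default to zero.

At 8 bits the accelerometer LSB is 0.125 g and the gyroscope LSB
15.6 deg/s — the dead band of the mid-tread quantizer around a static
operating point is then comparable to tremor amplitudes, which is what
drives the cross-sensor degradation results.

## Baseline task trajectories

Trials are synthesized at 1000 Hz (reference-grade rate) so every
downstream sensor model decimates. Each of the three clinical tasks has a
static hand posture, physiological sway, and (for the reaching task) a
voluntary movement profile:

| task | posture (roll, pitch) | position sway | orientation sway |
|---|---|---|---|
| rest | (25°, 0°) — hand relaxed on armrest | 1 mm | 0.5° |
| postural hold | (0°, −10°) — arm outstretched, palm down | 3 mm | 1.5° |
| finger-to-nose | (0°, −10°) start + reach motion | 3 mm | 1.5° |

Sway is band-limited Gaussian drift (2nd-order Butterworth, 1.5 Hz
corner) scaled to the target standard deviation. The finger-to-nose task
repeats 0.35 m minimum-jerk out-and-back reaches on a 4 s cycle (15 per
60 s trial, well above the clinical minimum of three), with a 20° pitch
excursion tracking the reach. All amplitudes are free parameters of the
generator (`MotionParams`): the original clinical recordings report no
kinematics, so these are plausible physiological scales, chosen once.
The distinct static postures matter: gravity projects differently onto
the body axes per task, which is how a classifier can separate the two
otherwise similar static tasks — exactly the information a real
wrist-worn sensor would see.

Conversion to inertial data uses second-order central differences for
position and quaternion derivatives. Body specific force is
`R(q)^T (p'' - g) / 9.80665` with the world frame z-up, so a static
sensor reads exactly (0, 0, +1) g; body angular velocity is
`2 * vec(q* ⊗ q')`; the magnetometer projects a constant mid-latitude
field (20, 5, −45) µT. Quaternions are stored (x, y, z, w) and must be
unit norm to 1e-8.

## Tremor model

Tremor bursts are multisine signals: per axis, 3 components with
frequencies drawn uniformly in the class band (rest 4–7 Hz, postural
5–8 Hz, kinetic 8.5–9.5 Hz — the "around 9 Hz" class needs a finite width
for frequency to be randomizable), independent phases, and component
amplitudes uniform in `range/3` so the per-axis amplitude total always
falls in the configured range (accelerometer 0.05–0.3 g, gyroscope
10–60 deg/s by default; visible above the wearable's noise floor, far
from range saturation). Each 60 s trial receives five 2 s bursts at
uniformly random disjoint positions, with a 10 ms raised-cosine taper at
burst edges to avoid spectral splatter. Outside bursts the record is
bit-identical to its input; the magnetometer is untouched. Component
draws are independent per axis (a flag shares them across axes).

## Dataset protocol

Each task is paired with the tremor class it elicits (postural->PT,
finger-to-nose->KT, rest->RT). Windows are 2 s with 1 s overlap
(59 windows per 60 s trial); a window takes the trial's tremor label when
its intersection with a burst is at least half the window, else class 1
(no tremor). Class numbering follows the reporting convention
1 = none, 2 = postural, 3 = rest, 4 = kinetic (configurable). The raw
protocol is heavily class-1 dominated; balancing down-samples every class
to a common per-class count (`balance_target / 4`, capped by the smallest
class) with a seeded draw, and never relabels. The split is stratified
70/30. Seeding uses `SeedSequence` spawn keys per (task, trial), with the
sensor-noise stream drawn identically for every sensor preset, so
cross-sensor experiments compare the same trials, the same tremor events
and the same underlying noise through different metrological models.

## Features, scaling, classifier

Eleven features per channel per window (time domain: mean, mean of
absolute values, squared sums below the 25th and 75th percentile,
sub-2 Hz and supra-2.5 Hz energies; autocorrelation: lag and height of
the first peak after the first zero crossing; frequency domain: dominant
frequency, amplitude sum and peak count below 5 Hz). Conventions that the
source description leaves open, fixed here: "mean" and "average" are the
arithmetic and rectified means; "maximum frequency in the spectrum" is
the frequency of the maximum-magnitude bin; percentiles are linear
interpolation on signed values; energies, autocorrelation and the
spectrum are computed on the de-meaned window (so translation affects
only the amplitude features); the spectrum is Hann-tapered and scaled to
sinusoid amplitude; spectral peaks must exceed 10% of the spectral
maximum; band filters are 4th-order zero-phase Butterworth. A degenerate
(zero-variance) window reports autocorrelation (window length, 0).

Features are concatenated across channels (6 channels -> 66 features;
accelerometer-only -> 33). Z-score scaling uses the training split's mean
and population standard deviation for both splits (no leakage);
zero-variance features map to 0 with a warning.

The classifier is a Gini CART tree capped at 100 splits
(`max_leaf_nodes = 101`), no pruning — the documented meaning of the
"fine tree" GUI preset — deterministic under a fixed random state.
Metrics are one-vs-rest precision, recall and F1 from the confusion
matrix, plus overall accuracy `trace(C)/sum(C)`, all in percent; a class
absent from the test set reports zeros and is flagged.

## Validation figures of merit

Two aligned signals are min-max normalized independently, then compared
by Pearson correlation (population moments) and RMSE, both x100. Records
at different rates are compared at the lower rate, with an optional
cross-correlation lag search for alignment. Comparing an ideal
reference-rate trace against its own wearable-model perturbation lands in
the Pearson > 90% / RMSE < 10% regime on every axis, which is the
qualitative regime reported for real device pairs; the exact published
table values depend on hardware recordings that were never released.

## Study problem sizes

The full protocol (1000 trials per task, ~10,000 balanced windows) is
scaled down to 200 trials per task (~8,000 balanced windows after
per-class capping) for the main study runs, and to 50 trials per task for
the 10-seed sign sweeps; these sizes are the package's default study
scale and are set in `tests/test_acceptance.py` and
`scripts/acceptance.py`. Accuracy at 200 trials per task sits within
about one point of the 100-trial value in our runs, so the scaling is not
the dominant error source.

## What the generator does not emulate

* Real recorded baselines: the published study fed the simulator with
  reference-device recordings; here trajectories are synthetic, so
  absolute feature scales (and therefore exact accuracies) differ.
* Healthy physiological tremor (8–12 Hz, sub-pathological amplitude) is
  absent: class-1 windows are cleaner than real data, which makes
  tremor-vs-none separation somewhat easier than in the field.
* No amplitude-to-severity (UPDRS score) mapping; no suppression of rest
  tremor during voluntary movement; no magnetometer error model; no
  orientation-fusion filter (a property of the commercial reference
  device, not of the simulator).
* Tremor amplitude ranges are a documented default, not a calibrated
  value: the literature source the published study cites for amplitudes
  prints none. Results that hinge on amplitudes relative to the 8-bit
  quantization dead band (the best/worst collapse in particular) are
  sensitive to this choice; see the limitations below.

## Known limitations

* The best/worst (train 16-bit, test noisy 8-bit) degradation reproduces
  qualitatively (accuracy drops, static-task tremor classes leak into
  class 1 through the quantizer dead band) but not to the published
  severity: with the default amplitude ranges most bursts remain above
  the 8-bit dead band, so the collapse is partial. A full collapse would
  require amplitudes mostly below ~0.06 g / ~8 deg/s, which would
  contradict the stated default.
* Gyroscope and accelerometer channels are individually almost
  sufficient on synthetic baselines, so the marginal value of adding
  gyroscope channels is smaller (and noisier across seeds) than in the
  published study.
* Bias instability is Gauss–Markov, not true 1/f; its Allan-variance
  signature differs away from the correlation time.
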