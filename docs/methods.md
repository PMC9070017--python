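# Methods

This note documents the models, defaults and numerical choices behind
the package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task model

A calibration consists of `n_trials` trials. Each trial is a 1 s target
prompt, a 500 ms fixation cross, a sequence of `seq_len` letters at the
presentation rate (stimulus-onset asynchrony 1000/rate ms, no gaps
within the sequence), and a 750 ms blank inter-sequence interval.
Exactly one letter per sequence is the target; its position is drawn
uniformly over the sequence (the randomization scheme is not dictated
by the task itself; uniform placement is the common calibration
convention). Sequence letters are drawn without replacement from the
28-character alphabet so the target letter appears exactly once. The
default calibration (100 trials × 10 letters) yields 100 target and
900 non-target events. The recording is padded 1.5 s past the final
trial so the widest analysis epoch fits around every event.

Time convention, used everywhere: milliseconds relative to stimulus
onset, onset = 0, pre-stimulus negative; sample windows are half-open
`[start, end)` and the onset maps to the sample at t = 0.

## Synthetic EEG generator

The generator (`sim.SimParams`) is a signal-level emulation, not a
cortical model. Its defaults define the reference scenario used by the
test suite; they were fixed once, from the phenomenology the analyses
must detect, and are not tuned per test.

| parameter | default | meaning |
| --- | --- | --- |
| `iaf_hz` | 10.0 Hz | alpha oscillator frequency |
| `alpha_amp` | 4.0 uV | alpha amplitude at the strongest channel (Oz) |
| `alpha_env_mod` | 0.3 | fractional slow (<1.5 Hz) envelope modulation |
| `erd_depth` (d) | 0.5 | fractional envelope attenuation after targets |
| `erd_window_ms` | 300–800 | latent attenuation window after target onset |
| `erd_ramp_ms` | 50 | raised-cosine on/off ramps of the attenuation |
| `n200_amp`, `p300_amp` | 5, 10 uV | ERP template amplitudes |
| `n200_lat_ms`, `p300_lat_ms` | 250, 375 | template peak latencies (centers of the detection windows) |
| `erp_sigma_ms` | 25 | Gaussian template width |
| `ssvep_amp` | 2.0 uV | steady-state fundamental at the strongest channel |
| `ssvep_harmonics` | (0.6, 0.4) | 2nd/3rd harmonic relative amplitudes |
| `noise_amp` | 4.0 uV | broadband RMS of the 1/f background |
| `noise_exponent` | 1.0 | power-law slope of the noise PSD |
| `blink_rate_per_min` | 0 | blink transients (150 uV, 400 ms, frontal) |
| `fs` | 300 Hz | acquisition rate |

Rationale for the main choices:

* **Alpha and ERD.** The alpha component is a single sinusoid with a
  multiplicative slow random envelope (alpha waxes and wanes; the
  envelope modulation also gives the baseline Z-statistics realistic
  variance). After each target the envelope is multiplied by
  `1 − d` inside the ERD window with 50 ms raised-cosine ramps: only
  the *measurement* window is prescribed by the analysis, so the latent
  time course is a package choice; a ramped plateau is the simplest
  course consistent with the measured effect window. `alpha_amp /
  noise_amp = 1` keeps the spectral alpha peak prominent but not
  caricatured.
* **SSVEP.** During each sequence, sinusoids at the presentation rate
  and its 2nd/3rd harmonics, phase-locked to the sequence start, gated
  with 50 ms ramps. At 4 Hz the 8 and 12 Hz harmonics bracket the alpha
  band, which is exactly the contamination the IAF masking and the
  rate-dependence analyses must handle.
* **ERPs.** Gaussian bumps (sigma 25 ms) added on target epochs only:
  a posterior negativity at 250 ms and a Pz-dominant positivity at
  375 ms — the centers of the N200 (200–350 ms) and P300 (300–450 ms)
  detection windows.
* **Blinks** default to zero: the task instructs participants to blink
  only between sequences, and the clean reference scenario doubles as
  the false-positive control for the artifact rules. Blink content is
  exercised explicitly (`blink_rate_per_min > 0`, `inject_artifacts`).
* **Artifact injection** uses band-limited bursts (10/15/40 Hz,
  raised-cosine gated) rather than raw steps, because flagging operates
  on 1–45 Hz filtered data and an out-of-band step would not survive
  preprocessing. Injections exceed their rule threshold by a
  configurable margin (default 20%). A large fast burst necessarily
  violates several rules at once; the ground-truth list records the
  intended rule, the flagger may report a superset.

What the generator does **not** emulate: non-stationary drowsiness
drifts, topographic detail beyond fixed per-channel gains, saccades,
heartbeat, line-noise harmonics beyond 60 Hz, inter-trial ERP latency
jitter, or any coupling between alpha state and ERP amplitude. Passing
tests therefore demonstrate correctness of the *analysis machinery*
under known ground truth, not performance on scalp recordings —
absolute effect sizes and classifier accuracies on this synthetic data
sit above what real recordings yield.

## Preprocessing

Zero-phase (forward–backward) order-8 Butterworth band-pass 1–45 Hz:
6 dB/octave per order gives the quoted 48 dB/octave as the one-way
design slope. The 60 Hz notch is a second-order IIR notch with quality
factor 30 (no width is dictated; Q = 30 is a conventional narrow
notch), applied after the band-pass (ordering is immaterial for linear
filters). Downsampling 300 → 150 Hz uses a polyphase resampler; the
preceding 45 Hz low-pass already guarantees anti-aliasing. The pooled
occipitoparietal signal is the samplewise mean of Pz, Oz, PO7, PO8,
appended as a virtual `POOL` channel; pooling commutes with the linear
filters (checked numerically). All filters run on the continuous
recording; epochs are cut afterwards.

## Spectrum and IAF

The per-calibration spectrum is the mean single-sided FFT amplitude
over all 2.5 s epochs of both classes, with a Hann taper over the outer
20% of each epoch (a Tukey window — 10% per edge; the "total vs per
edge" reading of a 20% taper is a dialect choice, noted here), an
amplitude correction of `1/sqrt(mean(w^2))` compensating the taper's
variance loss, and normalization so band amplitude over 4–20 Hz sums
to 1 (a max-normalized variant is selectable).

IAF selection searches 7.5–12.5 Hz for local maxima and discards
candidates that (a) lie within ±0.25 Hz of a presentation-rate harmonic
(k·rate, k = 1..3), (b) have prominence below 5% of their own height,
or (c) fall below 1.5× the median band amplitude. Criterion (c) is the
deterministic replacement for the original visual rejection of noise
peaks: stochastic spectra always contain locally prominent ripple, so a
prominence rule alone cannot trigger the fallback; a genuine alpha
prominence stands several times above the band floor while ripple and
harmonic-line skirts do not. With no qualifying peak the estimate falls
back to 10 Hz (a 10 Hz layer with ~4 Hz spectral bandwidth covers most
of the alpha band). Winning frequencies are rounded to the nearest
0.5 Hz.

## Wavelet transform and attenuation

48 layer frequencies `f_k = 4 · 4^((k−1)/47)`, k = 1..48 (log-spaced,
endpoints included). Each layer is a complex Morlet wavelet with
parameter c = 5, scaled to unit energy (L2). The transform is computed
as a zero-padded FFT filterbank using the analytic one-sided Gaussian
frequency response, so there is no time-domain truncation; output is
complex magnitude (the envelope reading of "real-valued voltage";
attenuation semantics require an envelope, and a config-selectable
real-part variant exists in the pywt-parameterized transform).

**Scale map.** With unit-energy normalization the magnitude response of
a layer to a pure tone peaks at scale `s = (c + δ)/ω`, δ =
(√(c²+2) − c)/2 ≈ 1/(2c), not at `c/ω`. The package maps layer
frequency to scale with that δ included, so each layer's response is
maximal exactly at its nominal center frequency (the conventional map
differs only at O(1/c²) ≈ 2% at c = 5). Without this calibration a
tone at a layer frequency localizes one layer low, because the √s
energy factor tilts the scale profile.

Z-transform: per epoch, channel and layer, `z = (x − μ_b)/σ_b` with
baseline statistics from that epoch's own −600..−100 ms samples
(per-epoch, not pooled: the baseline belongs to its test epoch).
Epochs with zero baseline deviation are excluded as degenerate and
logged. Alpha activity is the mean Z over 300–800 ms at the IAF layer;
the attenuation effect is the target-minus-non-target difference of the
class medians; within-calibration inference uses a two-sided
Mann-Whitney U test on the per-epoch values. The 2.5 s epoch leaves a
250 ms edge buffer beyond the ±1 s analysis range; the lowest layers'
wavelet support exceeds that buffer, so samples outside ±1 s are
edge-contaminated at 4 Hz and are never measured.

ERD depth recovery (`estimate_erd_depth`) divides the class-average
magnitude time courses and returns one minus the minimum of the
target/non-target ratio inside the response window: ramps and wavelet
smoothing dilute a window-*mean* estimate of the latent depth, while
the plateau center retains it.

## ERP analysis

1 s epochs (−200..+800 ms), baseline-corrected to the −200..0 ms mean,
averaged per class. N200 = most negative sample 200–350 ms, P300 = most
positive sample 300–450 ms, both on the target average (fully
automatic; ties break to the earliest latency). Amplitudes for both
classes are the mean over ±4 samples (~53 ms at 150 Hz) around the
target-derived latencies. Note the windowed mean deliberately smooths:
for a Gaussian peak of sigma 25 ms it retains ~80% of the peak value
(the exact 9-point Gaussian mean), so template recovery is assessed on
the waveform peak, not the windowed measure.

## Artifact rules

Per channel over the full epoch, any-channel/any-rule flags the epoch:
gradient > 50 uV/ms between adjacent samples; range > 125 uV within any
sliding 50 ms window; |x| > 75 uV; range < 0.5 uV over any contiguous
≥100 ms window. Windows step one sample and round to the nearest sample
count. All seven channels are checked by default (conservative;
configurable). Rejection is **off** by default in the pipeline — the
primary analyses keep all epochs — and the manual review step of the
original semi-automatic procedure is omitted.

## Classifiers

Features: the Z-scored IAF-layer time series over the response window,
concatenated across the four occipitoparietal channels (500 ms at
150 Hz × 4 channels = 300 features), never averaged. Models train with
inverse-frequency class weights and are scored by balanced accuracy.
Cross-validation (unspecified in the original design) defaults to 10
seeded stratified 80/20 train/test splits.

* Logistic regression (L2) and RBF SVC (C = 1; no kernel is dictated,
  RBF is the scikit-learn default) on standardized features.
* Tangent space: per-epoch 4×4 channel covariances over the response
  window; affine-invariant (Karcher) geometric mean of the training
  covariances as reference; log-map vectorization (off-diagonals ×√2);
  class-balanced logistic regression. Singular covariances are shrunk
  toward the scaled identity automatically and logged.
* Uniform random: predicts each class with probability 0.5 from the
  seeded generator, ignoring the features and the 9:1 prior.
* RDA/KDE reference (ERP route): 0..+500 ms epochs from a 2–45 Hz
  filtered recording, all 7 channels; PCA retaining 95% variance;
  regularized discriminant analysis with shrinkage λ = 0.9 toward the
  pooled covariance and γ = 0.1 toward the scaled identity; Gaussian
  KDEs (Silverman bandwidth) of the discriminant score per class;
  classify by log-density ratio at threshold 0. All four constants are
  config-exposed.

Window tuning varies the 500 ms baseline start over −1050..−600 ms and
the response start over +150..+550 ms (50 ms grid step → 10 × 9
points), re-Z-transforming and re-extracting features per grid point
and scoring a logistic-regression criterion model. By default the grid
is scored by cross-validation inside the training portion of a
stratified 80/20 split (nested; window selection never sees held-out
epochs); a plain mode scores the grid on the evaluation splits
directly. Ties break toward the default (−600, +300) pair.

## Null scenario and type-I control

The d = 0 null used for type-I checks also sets the ERP template
amplitudes to zero. A deterministic target-locked transient has
spectral support reaching into 4–16 Hz, so keeping the templates with
d = 0 would break class exchangeability at the alpha layer and test a
false null. SSVEP, alpha and noise are class-independent and stay on.

## Problem sizes and reproducibility

The repeated-simulation properties use full 100-trial calibrations (20
runs for the d = 0.5 detection-rate property, 40 for the type-I rate);
single-scenario checks use 20–60 trials, which the generator's effect
sizes make ample. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical seeds reproduce recordings
bit-for-bit, and the pipeline re-run on the same input reproduces every
output value.

## Known limitations

* The generator's effect sizes are homogeneous; there is no
  inter-individual variability model, so "participant-level" statistics
  (across-participant medians, correlations between effects) are
  supported by the `stats` module but not given reference values.
* The two Morlet parameterizations (unit-energy c = 5 filterbank vs
  PyWavelets `cmor1.5-1.0` with unnormalized scales) are both
  implemented and agree on peak location, but their amplitude scales
  differ by construction; which one matches the original numerics
  cannot be determined, and all Z-scored quantities are invariant to
  per-layer scale anyway.
* EDF output is 16-bit with a symmetric physical range derived from the
  recording extremum; quantization error is below 0.01 uV for typical
  amplitudes and is covered by the round-trip test.
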