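# Methods

This note documents the models, conventions and design choices behind
`gaitdemog`: what each stage computes, which knobs matter, what the
synthetic cohort generator does and does not emulate, and the numerical
conventions that affect reported values.

## Signal model and preprocessing

Input recordings are uniformly sampled six-channel time series: triaxial
acceleration in g and triaxial angular velocity in rad/s, 100 Hz, waist-worn
sensors with a fixed axis registry — x lateral, y vertical, z forward.
Axes are assumed pre-aligned to a common reference frame; orientation
estimation and resampling are out of scope. Timestamps in the CSV dialect
are used only to infer the sampling rate.

**Wavelet denoising.** Each channel is denoised by discrete wavelet
shrinkage: Daubechies-4 decomposition at level 3, soft universal threshold
σ·√(2 ln n) with σ estimated from the median absolute deviation of the
finest-scale detail coefficients (MAD/0.6745). These are standard
wavelet-denoising defaults; family, level and thresholding mode are
configurable. Denoising is applied to the whole recording *before*
windowing by default so that window edges do not create boundary
artifacts; a window-first variant is available via `denoise_first: false`.
Soft thresholding only shrinks coefficients, so output energy never
exceeds input energy, and a second pass is a near-fixed-point (the
residual details after shrinkage imply a near-zero second threshold).

**Net acceleration** is the per-sample Euclidean norm of the three
(denoised) acceleration axes. It is invariant to any rotation applied
jointly to the axes, which makes its peak structure robust to sensor
orientation.

**Windowing.** Windows are `round(window_s·rate)` = 300 samples (3 s) with
50% overlap, i.e. stride 150 samples; the window count for a recording of
L samples is `floor((L − W)/S) + 1`. Trailing samples that do not fill a
window are dropped — no padding — so every window has identical length and
hence identical spectral resolution. Each window inherits the recording's
labels and carries the per-window standard deviation of the denoising
residual per channel (exposed as `<channel>-res-std`; this is the package's
reading of the otherwise-undefined "res-std" feature: the spread of what
denoising removed, a local noisiness measure).

## Feature catalogue

All features are named `accl|gyro-axis-descriptor` (net acceleration is
`accl-net`); one window yields ≈590 named values. Missing values (too few
peaks, zero variance, zero spectral power) are NaN and median-imputed from
the training split at modelling time, so no window is dropped.

Conventions that affect values:

* **Peaks**: a positive peak is a local maximum above the channel mean
  (negative: minimum below the mean) with ≥200 ms separation between
  consecutive peaks — at human cadences (roughly 350–700 ms step
  intervals) this yields one peak per step and rejects ripple. Both the
  baseline rule and the separation are configurable. Unqualified "peak"
  features (`accl-y-peak-interval-std`) alias the positive maxima.
* **Peak intervals** are in milliseconds; interval standard deviations use
  the population (n-denominator) form. The interval mean needs ≥2 peaks,
  the interval std ≥3; otherwise the feature is missing.
* **Time-domain statistics**: MAD is the mean absolute deviation about the
  mean; IQR uses linear-interpolation quantiles; energy-per-second is
  Σx²/duration of the raw (denoised) signal including the gravity offset —
  no detrending. Skewness is the standardized third moment; kurtosis is
  excess (Fisher) kurtosis; both are moment (biased) estimators and are
  missing for zero-variance channels.
* **Jerk** is the first difference times the sampling rate (length n−1);
  the full time-domain + peak block is repeated on it with `-jerk-` names.
* **Spectra**: the FFT spectrum is one-sided |X|²/n with doubled interior
  bins, so total power equals signal energy (Parseval); the PSD uses
  Welch's method with 128-sample Hann segments and 50% overlap on the
  300-sample window (≥2 averages, 0.78 Hz bins, 0–50 Hz). Spectral moments
  treat the power-normalized spectrum as a distribution over frequency;
  spectral entropy is normalized by log(#bins) to [0, 1]. The bandwidth
  lower bound is the smallest frequency at which cumulative power reaches
  10% of the total; the upper bound applies the symmetric 90% rule (the
  upper rule is this package's interpretation — only the lower one has an
  established definition).
* **Bands**: Delta/Theta/Alpha/Beta/Gamma/Zeta are contiguous 3 Hz bands
  over [0, 18) Hz with inclusive-lower/exclusive-upper edges, computed on
  the Welch PSD; per band: total power, percentage of total spectrum power
  (0–100), and the frequency of maximum power. Percentage and bandwidth
  features are scale-invariant.
* **Correlation**: Spearman ρ is the Pearson correlation of average ranks
  (tie-aware; equal to the 1 − 6Σd²/(n(n²−1)) form when ties are absent),
  emitted for all 21 unordered component pairs in the fixed order
  accl-x, accl-y, accl-z, accl-net, gyro-x, gyro-y, gyro-z.

A note on axis semantics: published selected-feature tables occasionally
gloss `accl-x` as forward acceleration; this package follows the axis
registry above (x lateral, z forward) consistently and does not attempt to
resolve that discrepancy.

## Synthetic cohort generator

The generator is a validation fixture, not a biomechanical simulation: it
plants known, recoverable parameters with the demographic structure the
pipeline is meant to detect.

Waveform (per recording): the vertical channel is a 1 g gravity offset plus
one Gaussian pulse (σ = 50 ms) per step, with onsets spaced
`step_interval_mean` ± i.i.d. Gaussian jitter — one detectable peak per
step by construction. The forward channel is a step-frequency sinusoid
plus a 10.5 Hz tone carrying the fraction `hf_power_frac` of the channel's
signal power (the beta-band dial). Lateral acceleration and the three
gyroscope channels (forward tilt, lateral twist, vertical swing) are
sinusoids at the step or stride (half-step) frequency — so the lateral
twist channel's lower bandwidth bound tracks the stride frequency, lower
in males because their step interval is longer. White Gaussian noise is
added to every channel (`noise_sd`, in g / rad/s).

Sex-conditional parameters (adult means ± between-subject SD):

| parameter | male | female | unit | source |
|---|---|---|---|---|
| step_interval_mean | 466.81 ± 60 | 433.44 ± 60 | ms | emulated population group means |
| step_interval_jitter_sd | 92.47 ± 22.8 | 81.71 ± 22.94 | ms | emulated population group means |
| hf_power_frac | 0.065 ± 0.037 | 0.045 ± 0.033 | – | emulated population group means |
| vertical_amp | 0.55 ± 0.08 | 0.42 ± 0.08 | g | calibration choice |
| forward_amp | 0.34 ± 0.05 | 0.27 ± 0.05 | g | calibration choice |
| twist_amp | 0.75 ± 0.10 | 0.95 ± 0.10 | rad/s | calibration choice |

The three printed group gaps alone (step interval, jitter, beta fraction)
give a between-subject Bayes separability far below what real gait data
exhibits, because real gait differs between the sexes in many correlated
channels at once. The amplitude gaps are the generator's stand-in for that
richness: they were fixed once, on the qualitative grounds that males walk
with stronger steps and females with more pronounced lateral twisting, at
magnitudes that bring the cohort's end-to-end separability into the high
80s–low 90s — the regime the pipeline is designed to operate in. Sensor
position modulates amplitudes (−15% for center-worn sensors, which sit
farther from the legs).

Age trends are piecewise-linear multipliers/offsets: children (from age 2)
take much shorter, jerkier, noisier steps with more body swing and tilt;
adult gait is stable; beyond ~60 steps slow (+ up to 40 ms for males),
weaken (−20% amplitude) and get noisier. Female step interval declines
slowly after age 30. Exact knots are documented defaults in
`simulate.default_parameter_map`, chosen once as plausible shapes.

What the generator does **not** emulate: harmonic-rich real gait spectra,
left/right asymmetry, stride-to-stride correlation (jitter is i.i.d.),
non-stationarity, sensor drift/saturation, or any correlation between
channels beyond shared timing. Passing end-to-end tests therefore shows
that the pipeline recovers planted demographic structure of realistic
magnitude — not that it attains any particular accuracy on real data. Age
information in the default maps is deliberately subtle (a few trend
dials), so cohort-level age regression is weak; the age models are instead
validated on planted monotone feature→age designs, where the
distance-weighted kNN regressor reaches R² ≈ 0.95.

Seeding: one root seed; per-subject streams are derived from
(seed, subject index), so cohorts are order-independent and every artifact
is a pure function of (config, seed). Within a recording the RNG is
consumed in a fixed order (phases, step jitter, noise), so deterministic
dials like `hf_power_frac` can be varied under identical noise.

## Modelling protocol

**Split.** 70/30 at the subject level, stratified by sex: with 50%
overlapping windows, a window-level split would place fragments of the
same strides on both sides, which measurably inflates window-level
accuracy. A window-level split remains available (`by_subject=false`) for
comparison with protocols that split by sample.

**RFE.** Features are median-imputed and z-scored, then an estimator with
linear weights is refit, dropping the lowest-|weight| feature each
iteration (step configurable) down to 30. Sex uses logistic regression;
age uses a linear support-vector regressor — an RBF SVR has no per-feature
coefficients to rank, so the linear-kernel variant is the workable reading
of "RFE with SVR".

**Model zoo defaults** (seeded, single-threaded): LR C=0.1 (lbfgs);
SVC C=10 RBF with Platt probabilities; kNN k=3, Manhattan distance,
distance weighting; RF 100 trees without bootstrap; XGBoost 500×0.1
(depth 10, subsample 0.7) for sex and 300×0.1 (depth 10, subsample 0.8)
for age; LightGBM 500×0.1; SVR C=150, RBF, ε=0.001. Distance- and
margin-based models are z-scored; tree ensembles are not. Five-fold CV
scores on the training split can be recorded via `cv_folds=5`; grids
beyond these defaults are deliberately out of scope. Sex is encoded
male=1, female=0 (affects only score orientation).

**Stacking.** SVC, kNN and RF bases produce out-of-fold positive-class
probabilities (one column per base) over 5 CV folds; the LightGBM
meta-model (100×0.1, row subsampling 0.4 applied every round via
`subsample_freq=1` — in LightGBM the subsample fraction is inert without a
frequency) is trained on [OOF probabilities ‖ original features]
(passthrough, meta input width 33 for 30 features); the bases are then
refit on the full training split for the prediction path. The OOF folds
are **grouped by subject** whenever a subject key is available: with
window-level folds, windows of a subject inform their own out-of-fold
probabilities, the OOF columns (especially kNN's) look far stronger than
they are on unseen subjects, and the meta-model misweights them — in our
cohort experiments this cost the ensemble 2–5 accuracy points versus
grouped folds under the subject-held-out protocol.

**Leakage policy.** Imputer, scaler, RFE and all model fits see training
data only; the test suite verifies that corrupting the test partition
changes no fitted parameter.

## Evaluation

Classification reports accuracy, F1 for the male-positive class and
macro-averaged F1 (published tables report "F1" without orientation, so
both are carried), rank-statistic AUC (tie-corrected Mann–Whitney form,
identical to trapezoidal ROC integration) and 2×2 confusion counts; AUC is
missing when a class is absent. Regression reports MAE, MSE, RMSE and
R² = 1 − SS_res/SS_tot explicitly — all four, so no squared-versus-root
scale ambiguity can arise — with R² missing for constant truth.

Stratified reports: per-age-bin tables use decade bins with the sparse
elderly decades merged (1–10, …, 51–60, 61–80; configurable); every age
must fall in exactly one bin. The sensor-position comparison down-samples
every position to the smallest position's subject count (by subject,
seeded), then runs the identical split/train/evaluate protocol per
position; positions with fewer than two subjects are excluded with a
warning.

## Problem sizes and runtime

The shipped study sizes are desk-scale choices: the demo and validation
cohorts use 200–300 subjects with 15–30 s recordings (≈5–19 windows each,
≈2,000–5,700 windows, ≈590 features), RFE recovery uses 100 replicates of
a 500×100 planted design, and the planted-age design uses n=2000. A full
300-subject study (simulate → extract → select → train → evaluate) takes a
few minutes on one CPU.

## Known limitations

* The simulator's sinusoid-plus-pulse waveforms are far simpler than real
  gait; absolute accuracies on it do not transfer to real recordings.
* `accl-y-res-std` and the 90% bandwidth upper bound are documented
  interpretations of underspecified quantities.
* Peak-based interval features quantize at the 10 ms sample period.
* The Welch grid (0.78 Hz bins) quantizes bandwidth bounds; for an
  off-grid tone the 10%-cumulative lower bound can land in the bin
  adjacent to the tone's own bin (window leakage), which is the expected
  behaviour of the discrete cumulative-sum definition.
* No probability calibration, no deep models, no gait-event labelling, no
  sensor fusion; level walking only.
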