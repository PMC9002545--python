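# Methods

This note documents the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Signal model and preprocessing

A segment is a channels × samples matrix with a sampling rate, ordered
10–20 labels, and subject/condition tags.  Preprocessing is deterministic
and applied in a fixed order: (1) polyphase resampling to 128 Hz,
(2) common-average referencing over the loaded channel set, (3) a 0.1 Hz
high-pass.  The high-pass is a zero-phase (forward–backward) 4th-order
Butterworth: the effective magnitude response is 8th order and group delay
is zero, which matters for 20 s epochs where a causal 0.1 Hz filter would
smear a substantial fraction of the window.  Average referencing over the
loaded subset (9 channels in the default analyses) rather than a full
montage is a deliberate simplification; with sparse coverage the common
average is a biased estimate of a neutral reference, and results should be
read as referenced to the mean of the analysis montage.  Upsampling is
refused rather than interpolated.  Independent-component and EMG artifact
removal are out of scope: inputs are assumed to be artifact-reduced
segments, and the robust spectral estimator below is the defence against
residual transients.

## Robust multitaper spectrum

Each segment is cut into non-overlapping windows of `window_s` seconds
(default 2 s, giving a 0.5 Hz grid and 10 windows per 20 s epoch).  Each
window is multiplied by the first `n_tapers` (default 5) orthonormal sine
tapers, w_k[t] ∝ sin(πk(t+1)/(T+1)); sine tapers need no iterative solver
and have closed-form orthonormality, at the cost of slightly worse sidebands
than Slepian tapers.  One eigenspectrum per (taper, window) pair gives 50
estimates per frequency bin, combined either by the mean (the classical
multitaper estimate) or, by default, by the **median divided by ln 2**: for
Gaussian data each eigenspectrum bin is ≈ exponential, whose median is
ln 2 × its mean, so the correction removes the median's downward bias.  The
median's value is robustness: one large transient corrupts a few
taper×window estimates, which the median ignores but the mean averages in.
The ln 2 correction is exact only for exponential bins, i.e. Gaussian
signals; for strongly line-like spectra the median combiner distorts peak
shapes (it sits on taper sidebands), which is why peak-location and
calibration tests use the mean combiner, and why relative — not absolute —
band power is the downstream quantity.  Taper count, window length, and
combiner are all configuration; none of them is identified by the study
design this reproduces, so the defaults are stated here rather than claimed
as canonical.

Relative band power sums PSD bins with lo ≤ f < hi (the final band closed
at 45 Hz so shared edges are never double-counted) and divides by the
1–45 Hz total.  On the 0.5 Hz grid the flat-spectrum delta fraction is
6/89 ≈ 0.0674 rather than the continuum 3/44 ≈ 0.0682; the discrete
convention is used consistently.

## Higuchi fractal dimension

Curve lengths follow the canonical normalisation
L_m(k) = (1/k) · [Σᵢ |X(m+ik) − X(m+(i−1)k)|] · (N−1)/(⌊(N−m)/k⌋k), with
L(k) the mean over m = 1..k and D = −slope of the OLS fit of ln L(k) on
ln k for k = 1..kmax.  kmax = 6 estimates the slope reliably at the window
lengths used here.  The per-channel statistic is the mean over
non-overlapping 256-sample windows (2 s at 128 Hz: 10 windows per epoch,
≥ 42 points per decimated curve at k = 6); the trailing remainder is
discarded, and constant windows raise rather than return a sentinel.  The
estimator is exactly invariant to affine rescaling of the input.  Validation
uses surrogates with known dimension 2 − H: Weierstrass cosine sums
W(t) = Σⱼ λ^(−jH) cos(2πλʲt + φⱼ) with λ = 5 and enough terms that the top
component saturates the sampling resolution (random phases make replicates),
and fractional Brownian motion synthesised by circulant embedding of the
fGn covariance.  Observed recovery at N = 2048 is within ±0.01 of theory
for Weierstrass and ±0.03 for fBm, well inside the ±0.07/±0.12 bands the
tests enforce.

## Within-subject statistics

One-way repeated-measures ANOVA uses the textbook decomposition
SS_total = SS_subjects + SS_conditions + SS_error,
F = MS_cond/MS_error with df (c−1, (c−1)(n−1)), and partial eta squared
SS_cond/(SS_cond+SS_error).  No sphericity correction is applied — the
reported df are uncorrected by design; under the generator's null the
empirical type-I error is nominal (the synthetic conditions are
exchangeable), but real EEG with unequal condition correlations would need
a Greenhouse–Geisser-type correction this package does not provide.  The
multivariate test is the one-sample Hotelling T² on within-subject
difference scores (per region: contrasts 2D−EO and 3D−EO × 3 channels,
p = 6), reported as Wilks' Λ = 1/(1+T²/(n−1)) with exact
F = ((n−p)/p)·T²/(n−1), df (p, n−p) — (6, 9) at n = 15.  A zero mean
difference vector short-circuits to Λ = 1 without inverting the (then
singular) covariance.  Bonferroni post hoc tests multiply each of the three
pairwise paired-t p-values by 3 within a channel's family; no correction is
applied across the 9 channels × 5 bands families, matching per-site
reporting conventions (family-wise error across the whole table is
therefore not controlled — a deliberate scope choice).

## Classification

Features are the five relative band powers plus FD, each averaged over the
nine sites, standardised with training-split statistics.  The network is
6-6-2 with tanh hidden and output units, ±1 one-hot targets,
sum-of-squares error, and online backpropagation with momentum 0.9 on a
stratified random 70/30 split.  The 0.4 learning rate is an *initial* rate:
at a fixed 0.4 with momentum 0.9 the effective step is ~4× the gradient and
the tanh units saturate within a few epochs, freezing the error; the rate
is therefore annealed exponentially to 0.001 across the epoch budget
(default 500, early stop when the epoch error changes by < 1e-6).  Batch
gradients are available as an option.  Ties in the output argmax go to the
negative class for determinism.  The ROC score is the difference of the two
output activations; AUC is the trapezoidal integral over thresholds
(scikit-learn's `roc_auc_score`).  A single ~45-observation split yields
high-variance metrics, so a repeated-split mode averaging over re-seeded
splits is provided for synthetic benchmarks.

## Synthetic data: what it emulates and what it does not

Per channel, an epoch is Σ_bands a(band, region) × band-limited Gaussian
noise + background + occasional transients, in arbitrary units (only
relative quantities are analysed downstream).  Band noise is made by FFT
masking with a 1/f^(β/2) amplitude tilt *inside* the band: purely flat
in-band spectra concentrate too much power at the top of the wide beta and
gamma bands and push the windowed FD of the composite above the complexity
range the generator is meant to emulate, whereas tilted bands leave band
*totals* (hence relative power) unchanged.  The background is 1/f^β noise,
flat below 1 Hz, extending to Nyquist.  Transients are 0.1 s raised-cosine
pulses of 10× the clean channel SD, Poisson-placed at `artifact_rate`
(default 0.05/s, about one per 20 s epoch) — the disturbance the median
combiner is designed to resist.

Default condition profiles are solved from embedded reference group means:
per region, band amplitudes satisfy a_b² = c·T_b − g_b(β), where T_b is the
target relative power and g_b the background's band fraction computed from
the exact discrete spectral shape, with c chosen so all a_b² ≥ 0.  The
background exponents (EO 2.0, 2D 1.7, 3D 1.62) are calibrated once so that
the windowed Higuchi FD of preprocessed default epochs lands at the
reference complexity means (~1.58 rest, ~1.65 task).  Between-subject
heterogeneity is log-normal amplitude factors (SD 0.15) per band plus a
Gaussian background-exponent offset (SD 0.08), drawn once per subject and
shared across that subject's three conditions so within-subject contrasts
carry only condition effects.  Study sizes default to the published design:
15 subjects × 3 conditions × 9 channels, 20 s at 128 Hz.

Not emulated: blink/ECG topographies, volume conduction or inter-channel
correlation (channels are independent), cross-over order effects, and any
absolute amplitude scale.  Passing tests therefore demonstrate that the
*estimators and statistics* behave correctly on signals with the configured
spectral/fractal structure — not that real EEG satisfies the generative
assumptions.

## Problem sizes and tolerances

Validation batch sizes: 20 replicates for FD recovery and end-to-end
orderings, 100 segments for the robustness win-rate (≥ 95/100 required),
500 replicates for null calibrations (binomial 95% CI 0.031–0.069 around
α = 0.05), 500 for the Wilks p-uniformity KS check.  The null type-I
simulation runs the full generator→spectrum→ANOVA path on a reduced
two-channel montage: the statistic is univariate per channel, so montage
size does not affect its null distribution but dominates runtime.  Oracle
agreements (curve length, ANOVA sums of squares) are required to 1e-12 and
1e-10 respectively; probabilistic assertions use the tolerances above.

## Known limitations

* The median combiner's ln 2 correction assumes exponential bins; narrow-band
  deterministic components violate it, biasing line spectra (not the noise
  floor).
* The one-sample Wilks construction needs p < n and a non-singular difference
  covariance; regions with collinear channels fail loudly rather than being
  regularised.
* The Bonferroni family is per channel; table-wide multiplicity is
  uncontrolled by design.
* The MLP is intentionally small and its single-split metrics are noisy;
  conclusions about contrast orderings are only stable across repeated
  splits/studies.
* EDF support is read-only; the writable interchange format is the CSV+JSON
  fixture pair.
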