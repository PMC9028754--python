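# Methods

## Model

The wake-up classifier is a bank of C Gaussian mixture models, one per ictal
state class, over N = 4 window features (peak-to-peak voltage; alpha,
low-gamma, and high-gamma power fractions). All mixtures share the same
cluster count K, and all covariances are diagonal, so each component density
factors into N univariate Gaussians — the structure the analog hardware
exploits, since a univariate Gaussian is one bump circuit and a product of N
of them is one cascade. Inference is maximum likelihood: the predicted class
is the argmax of the per-class mixture densities, with ties broken toward the
lowest class index (class 0 is pre-ictal, the alarm-raising class).

Assumptions worth stating: features within a window are treated as
mixture-of-Gaussian distributed per class and windows as i.i.d. (no temporal
model); the two trained classes are pre-ictal and inter-ictal only — ictal and
post-ictal windows never enter training and are excluded from both metrics,
because the wake-up front-end's job ends at the seizure onset.

## EM training

Mixtures are fitted per class by expectation-maximization:

- **Initialization** — a k-means partition of the class's data
  (scikit-learn KMeans, one start, fixed seed) provides initial means,
  per-cluster variances, and proportions. Everything downstream is
  deterministic given the seed.
- **Convergence** — relative change of mean log-likelihood below 1e-6, or 500
  iterations. The per-iteration log-likelihood trace is available
  (`fit_em(..., return_trace=True)`) and is non-decreasing, the standard EM
  guarantee, asserted in the tests.
- **Variance floor** — component variances are floored at 1e-6 times the
  *per-dimension variance of the training data* (absolute fallback 1e-18 for
  degenerate all-identical inputs). The floor is relative because the four
  features live on very different scales: peak-to-peak voltage is ~1e-4 V
  (variance ~1e-10 V²) while the band fractions are order-one. Any absolute
  floor large enough to be meaningful for the fractions would swamp the
  voltage feature's true variance and effectively delete it from the model.
- **K = 1** is handled in closed form (sample mean, biased sample variance).
  K exceeding the sample count is an error. K itself is a hyperparameter of
  the architecture, chosen by the user (default 2).

## Analog behavioral model

The analog stage is modeled at equation level — steady-state currents as real
numbers — not at transistor level; no noise, temperature, settling, or layout
parasitics.

- **Bump law** — `I(v) = I_bias · sech²((v − V_r)/(2 n U_T w(V_c)))` with
  slope factor n = 0.7, thermal voltage U_T = 25.85 mV, supply ±0.3 V. The
  sech² transfer is the classic subthreshold differential-pair/current-
  correlator response: even about V_r, unimodal, peak = I_bias, and its
  best-fit Gaussian over ±4 effective σ has R² ≈ 0.996.
- **Width law** — `w(V_c) = exp((V_c − c0)/c1)`, c0 = 0 V, c1 = 0.3 V:
  positive, smooth, monotone. The map from V_c to the *effective Gaussian σ*
  (in volts) is calibrated numerically: bump curves are fitted with
  least-squares Gaussians on a 25-point V_c grid spanning the rails, and the
  tabulated map is interpolated both ways. Out-of-range σ requests clamp to
  the calibrated range with a warning.
- **Cascade** — N bumps in sequence, each biased by its predecessor's output,
  give `I_bias(first) · Π_n s_n(v_n)` with unit-peak shapes s_n; the closed
  form and an explicit stage-by-stage simulation agree to 1e-9 relative.
- **GMM → circuit mapping** — per dimension, V_r = scaled component mean and
  V_c = inverse width map of the scaled component σ. The feature scaler maps
  each training feature's [1st, 99th] percentile range affinely onto
  [−150 mV, +150 mV], leaving headroom to the rails; out-of-range inputs clamp
  with a warning. The cluster bias current encodes
  `w_i · Π_n (√(2π) σ_n)⁻¹` — weight *times the Gaussian normalizers* — then
  all currents are normalized so the largest equals the 12 nA full scale.
  Including the normalizers keeps the summed class current proportional to the
  class likelihood even when clusters have different widths; encoding the
  weight alone would make wide clusters loom too large. A `tied_weights` mode
  instead forces equal bias currents within each class, mirroring hardware
  that provides only one bias source per class (the 34-parameter budget:
  C·K·N mean voltages + C·K·N width voltages + C bias currents); free
  per-cluster weights remain the software default.
- **WTA** — ideal hard argmax: the winner's output equals the WTA bias
  current, losers are exactly 0 (an optional finite-gain soft mode leaves
  losers a residual, always below the 100 pA logical-zero threshold). Ties go
  to the lowest index, matching the ideal classifier.

## Operation and parameter accounting

The operation count uses a fixed convention: one univariate Gaussian
evaluation costs 8 scalar operations (difference, square, scale by the
precomputed inverse variance, halve, negate, exponentiate, scale by the
precomputed normalizer, multiply into the running product), cluster summation
costs K−1 additions per class, and the argmax costs C−1 comparisons:
`8·C·K·N + C·(K−1) + (C−1)`, which is 131 for (C, K, N) = (2, 2, 4).
Parameters count `2·C·K·N + C` = 34 for the same architecture. Power figures
(180 nW analog, 166 K classifications/s, 3.07 µW digital back-end) are
configuration inputs for the accounting and duty-cycle model, never computed.

## Mismatch Monte-Carlo

Process variation is abstracted as independent Gaussian perturbations per
bump: an additive V_r offset (σ = 2 mV), and multiplicative gains on the
effective width and the bias current (σ = 2% each). These magnitudes are
typical subthreshold matching scales and are fully configurable; they are an
abstraction of the package, not calibrated against any specific process. Each
Monte-Carlo run is deterministic given (seed, run index); the reported
statistic is the per-run specificity distribution (list, mean, std). Zero
sigmas reproduce the unperturbed specificity exactly.

## Evaluation semantics

Windows are labeled by start time; pre-ictal spans [onset − 1 h, onset),
post-ictal [offset, offset + 1 h), with precedence
ictal > pre-ictal > post-ictal > inter-ictal when periods overlap (predicting
an imminent seizure outranks recovering from the last one). Sensitivity is
alarm-based — a seizure is predicted iff at least one alarm window falls in
its pre-ictal period — and undefined (NA) without seizures. Specificity is
TN/(TN+FP) over inter-ictal windows only. An alarm is by default any window
classified pre-ictal; a consecutive-window smoothing parameter m (default 1)
is exposed. The duty-cycle model charges the digital back-end for all
pre-ictal time plus the false-positive share of the rest:
`duty = pre_frac + (1 − pre_frac)(1 − specificity)`.

## Feature extraction

4 s windows with 2 s stride at 256 Hz (alpha gets ≥ 32 cycles per window);
single-taper Hann periodogram; band fractions are in-band power over total
power on (0, fs/2], DC excluded for electrode-offset robustness. Band edges:
alpha 8–13 Hz, gamma 30–100 Hz split at 65 Hz. All configurable. A constant
window has zero AC energy and its fractions are defined as 0.

## Synthetic data

The feature-level generator draws per-window vectors from per-class
ground-truth mixtures (K = 2, N = 4) whose class means are separated by more
than 4 per-dimension standard deviations — the well-separated regime the
wake-up architecture targets — with scalp-realistic scales (inter-ictal
~60–90 µVpp, alpha-dominant; pre-ictal larger, gamma-shifted). The default
scenario is a 24 h record with 4 seizures of 60 s separated by ≥ 2.5 h, so
one-hour pre/post periods never collide; seizures are placed one per
day-quarter with uniform jitter.

The signal-level generator synthesizes raw EEG as a sum of four unit-variance
band-limited Gaussian noise carriers (background 1–8 Hz, alpha, low gamma,
high gamma) constructed by spectral masking — which keeps carrier energy
strictly in-band so extracted fractions recover the per-state targets within
±0.05 — under per-band gain envelopes `amplitude · √fraction` that follow the
ictal state with 10 s smooth crossfades. Ictal segments get a high-amplitude
gamma-dominant profile but are placeholders: ictal waveform morphology
(spikes, rhythmic discharges) is deliberately not modeled, as those windows
never enter training or evaluation.

What passing on this data does and does not show: the synthetic generators
produce exactly the class-conditional structure the model assumes, so results
(e.g. 100% sensitivity, ~100% specificity) demonstrate the correctness of the
pipeline and the fidelity of the analog approximation, not clinical
performance. Real EEG features are heavier-tailed, non-stationary, artifact-
laden, and far less separable; specificity near 70% rather than 100% is the
realistic regime there.

## Problem sizes

Default test and acceptance runs use the 24 h scenario (43 199 windows of
4 s / 2 s stride), a 50/50 stratified train/test split, EM with K = 2 on the
~18 700 training windows of the two trained classes, and Monte-Carlo batches
of 100 runs on 2 000–4 000 windows. Raw-signal closed-loop checks use 3 h
records at 256 Hz. These sizes keep the full suite under a minute on one CPU.

## Known limitations

- No transistor-level effects: the sech²/width-law pair is a behavioral
  abstraction, and mismatch magnitudes are nominal, not process-calibrated.
- Single channel, no artifact rejection or signal-quality gating.
- Train/test is a window-level stratified split, not patient-level
  cross-validation; with i.i.d. synthetic windows this is sound, but it would
  leak temporal correlation on real recordings.
- The alarm model has no latency or refractory semantics beyond the optional
  consecutive-window smoothing.
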