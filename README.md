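# gmmwake

Software model and evaluation pipeline for a **nanopower analog Gaussian-mixture
wake-up classifier** for epileptic seizure prediction from single-channel EEG.

Embedded seizure-prediction devices face a power wall: accurate digital
inference engines draw microwatts to milliwatts, which limits battery life for
always-on wearables. A wake-up architecture puts an ultra-low-power analog
classifier in front: it runs continuously on four cheap features per analysis
window — the signal's peak-to-peak voltage and the power fractions in the alpha
band and the lower/upper halves of the gamma band — and only switches on the
power-hungry digital back-end when a pre-ictal (seizure-imminent) state is
suspected. The front-end must therefore have very high sensitivity (never sleep
through a pre-ictal period) while its specificity directly sets how long the
back-end stays off.

This package implements that system end to end, exercisable entirely on
synthetic data:

- **Ideal classifier** (`gmmwake.gmm`) — per-class Gaussian mixtures with
  diagonal covariance. Class c models the feature density
  `p(x | λ_c) = Σ_i w_i^c Π_n N(x_n | μ_n^i, (σ_n^i)²)`, fitted by
  expectation-maximization; classification is `argmax_c p(x | λ_c)`.
- **Analog behavioral model** (`gmmwake.analog`) — the circuit-level
  realization at equation level: each univariate Gaussian is a subthreshold
  bump stage `I(v) = I_bias · sech²((v − V_r)/(2 n U_T w(V_c)))`; cascading N
  stages multiplies their curves (a diagonal-covariance multivariate bump),
  current mirrors sum the K cluster currents per class, and a winner-take-all
  stage outputs the argmax as a logical current (winner ≈ bias current, losers
  < 100 pA). Includes the GMM→circuit parameter mapping, width calibration, and
  device-mismatch Monte-Carlo analysis.
- **Feature pipeline** (`gmmwake.features`) — windowing and periodogram
  band-power extraction from raw EEG (CSV, or EDF via the optional `mne`
  extra).
- **Evaluation** (`gmmwake.evaluate`) — ictal-state labeling around annotated
  seizures (pre-/post-ictal default one hour each), alarm-based sensitivity
  (a seizure counts as predicted if ≥ 1 alarm falls in its pre-ictal period),
  window-based specificity over inter-ictal time, and the wake-up duty-cycle
  power model.
- **Synthetic data** (`gmmwake.simulate`) — day-scale seizure timelines,
  per-window features from ground-truth mixtures, and raw EEG as state-modulated
  band-limited noise.
- **CLI** (`gmmwake.cli`) — `simulate`, `extract-features`, `train`,
  `map-analog`, `evaluate`, `montecarlo`, `report`.

## Worked example

Simulate a 24 h single-channel record with 4 seizures, train the two-class
(pre-ictal vs inter-ictal) mixture classifier with K=2 clusters per class, and
evaluate the analog realization:

```sh
$ gmmwake simulate --out-dir demo --duration 86400 --n-seizures 4 --seed 1
seed=1 windows=43199 seizures=4
$ gmmwake train --features demo/features.csv --out demo/model.json --seed 1
trained C=2 K=2 N=4 -> demo/model.json
$ gmmwake evaluate --model demo/model.json --features demo/features.csv \
      --timeline demo/timeline.csv --duration 86400 --mode analog
sensitivity       : 1.0
specificity       : 1.0
predicted seizures: 4
missed seizures   : 0
true negatives    : 30159
false positives   : 0
back-end duty     : 0.1667
system power      : 0.6917 uW
```

All 4 seizures are predicted (an alarm in every one-hour pre-ictal period) and
no inter-ictal window raises a false alarm, so the digital back-end only runs
during the pre-ictal sixth of the day: duty cycle 0.167, total system power
0.69 µW against 3.25 µW with the back-end always on. On this well-separated
synthetic scenario the analog decisions agree with the ideal ones on every
window; real EEG is harder (see `docs/methods.md`).

Architecture accounting for the reference 2-class, 2-cluster, 4-D classifier:

```sh
$ gmmwake report
n_parameters                : 34
n_operations                : 131
energy_per_classification_j : 1.08434e-12
energy_per_operation_j      : 8.27738e-15
...
```

i.e. 34 control parameters (two voltages per bump plus one bias current per
class), 131 scalar operations per classification, and — at the hardware's
180 nW / 166 K classifications per second — about 1.1 pJ per classification or
8.3 fJ per operation.

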