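"""Synthetic inputs with the statistical structure the classifier assumes.

Two generators are provided, matching the two entry points of the
pipeline:

* feature-level — draw 4-D feature vectors directly from per-class
  Gaussian-mixture ground truth (pre-ictal vs inter-ictal), either as
  plain labeled tables or arranged on a seizure timeline window by
  window;
* signal-level — synthesize raw single-channel EEG as a sum of
  band-limited Gaussian noise whose per-band gains follow the ictal
  state, so that windowed band-power features recover the per-state
  targets.

The default scenario mirrors a day-scale recording: 24 h at 256 Hz with
4 seizures separated by gaps of at least 2.5 h, so the one-hour
pre-/post-ictal periods never collide.  All generators are
bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .evaluate import (
    ICTAL,
    INTER_ICTAL,
    POST_ICTAL,
    PRE_ICTAL,
    SeizureTimeline,
    label_timeline,
)
from .features import FEATURE_COLUMNS, BandSpec
from .gmm import ClassGMM, GaussianComponent

__all__ = [
    "StateProfile",
    "EEGSimSpec",
    "default_truth",
    "generate_features",
    "generate_timeline",
    "generate_window_features",
    "generate_eeg",
]


def default_truth() -> dict[str, ClassGMM]:
    """Ground-truth feature mixtures for the two classes (K=2, N=4).

    Feature order follows :data:`gmmwake.features.FEATURE_COLUMNS`:
    peak-to-peak voltage (volts) and the alpha / low-gamma / high-gamma
    power fractions.  Inter-ictal is alpha-dominant with scalp-scale
    amplitudes around 60-90 uVpp; pre-ictal shows suppressed alpha,
    elevated gamma, and larger amplitude.  Class means are separated by
    more than 4 per-dimension standard deviations, the well-separated
    regime the wake-up classifier is designed for.
    """
    inter = ClassGMM(
        label=INTER_ICTAL,
        components=[
            GaussianComponent(
                mean=[60e-6, 0.60, 0.05, 0.03],
                var=np.array([8e-6, 0.04, 0.015, 0.010]) ** 2,
                weight=0.5,
            ),
            GaussianComponent(
                mean=[90e-6, 0.50, 0.08, 0.05],
                var=np.array([8e-6, 0.04, 0.015, 0.010]) ** 2,
                weight=0.5,
            ),
        ],
    )
    pre = ClassGMM(
        label=PRE_ICTAL,
        components=[
            GaussianComponent(
                mean=[140e-6, 0.25, 0.22, 0.18],
                var=np.array([10e-6, 0.04, 0.020, 0.015]) ** 2,
                weight=0.5,
            ),
            GaussianComponent(
                mean=[180e-6, 0.18, 0.30, 0.25],
                var=np.array([10e-6, 0.04, 0.020, 0.015]) ** 2,
                weight=0.5,
            ),
        ],
    )
    return {PRE_ICTAL: pre, INTER_ICTAL: inter}


def _draw_from_mixture(gmm: ClassGMM, n: int, rng: np.random.Generator) -> np.ndarray:
    comps = rng.choice(gmm.n_components, size=n, p=gmm.weights)
    means = gmm.means[comps]
    stds = np.sqrt(gmm.variances[comps])
    return means + stds * rng.standard_normal((n, gmm.n_dims))


def generate_features(
    truth: dict[str, ClassGMM] | None = None,
    n_per_class: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """I.i.d. labeled feature draws from per-class ground-truth mixtures."""
    truth = truth or default_truth()
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for label in sorted(truth):
        X = _draw_from_mixture(truth[label], n_per_class, rng)
        n_dims = X.shape[1]
        cols = FEATURE_COLUMNS if n_dims == 4 else [f"f{i}" for i in range(n_dims)]
        df = pd.DataFrame(X, columns=cols)
        df["state"] = label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_timeline(
    duration: float = 86400.0,
    n_seizures: int = 4,
    seizure_dur: float = 60.0,
    min_gap: float = 9000.0,
    seed: int = 0,
) -> SeizureTimeline:
    """Random seizure placement with guaranteed spacing.

    Each seizure lands in its own ``duration / n`` segment, offset from
    the segment start by at least ``min_gap``; this guarantees gaps of at
    least ``min_gap`` both before the first seizure and between
    consecutive ones, so with the default 2.5 h gap the one-hour
    pre-/post-ictal periods are unambiguous.
    """
    if n_seizures == 0:
        return SeizureTimeline(duration=duration, seizures=[])
    if n_seizures * (seizure_dur + min_gap) > duration:
        raise ValueError(
            f"cannot pack {n_seizures} seizures of {seizure_dur}s with {min_gap}s gaps "
            f"into {duration}s"
        )
    rng = np.random.default_rng(seed)
    segment = duration / n_seizures
    slack = segment - seizure_dur - min_gap
    onsets = [i * segment + min_gap + rng.uniform(0.0, slack) for i in range(n_seizures)]
    return SeizureTimeline(
        duration=duration,
        seizures=[(o, o + seizure_dur) for o in onsets],
    )


def generate_window_features(
    tl: SeizureTimeline,
    truth: dict[str, ClassGMM] | None = None,
    win_len: float = 4.0,
    stride: float = 2.0,
    pre_dur: float = 3600.0,
    post_dur: float = 3600.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-window features on a labeled timeline.

    Windows tile [0, duration); each is labeled by its ictal state and its
    feature vector is drawn from that state's ground-truth mixture
    (ictal and post-ictal windows, which never enter training or
    evaluation, reuse the inter-ictal mixture).
    """
    truth = truth or default_truth()
    rng = np.random.default_rng(seed)
    n_windows = int(np.floor((tl.duration - win_len) / stride)) + 1
    starts = np.arange(n_windows) * stride
    labels = label_timeline(tl, starts, pre_dur=pre_dur, post_dur=post_dur)
    X = np.empty((n_windows, 4))
    for state in (PRE_ICTAL, INTER_ICTAL, ICTAL, POST_ICTAL):
        mask = labels == state
        if not mask.any():
            continue
        gmm = truth.get(state, truth[INTER_ICTAL])
        X[mask] = _draw_from_mixture(gmm, int(mask.sum()), rng)
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df.insert(0, "t_start", starts)
    df["state"] = labels
    return df


# ---------------------------------------------------------------------------
# raw-signal synthesis


@dataclass(frozen=True)
class StateProfile:
    """Band-power targets and amplitude of one ictal state.

    Fractions are of total signal power; whatever they leave over goes to
    a low-frequency background band.  ``amplitude`` is the overall signal
    standard deviation in volts.
    """

    alpha_frac: float
    gamma_lo_frac: float
    gamma_hi_frac: float
    amplitude: float

    def __post_init__(self) -> None:
        s = self.alpha_frac + self.gamma_lo_frac + self.gamma_hi_frac
        if s > 1.0 + 1e-12:
            raise ValueError(f"band fractions must sum to <= 1, got {s}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def background_frac(self) -> float:
        return max(1.0 - self.alpha_frac - self.gamma_lo_frac - self.gamma_hi_frac, 0.0)


def _default_profiles() -> dict[str, StateProfile]:
    inter = StateProfile(alpha_frac=0.55, gamma_lo_frac=0.06, gamma_hi_frac=0.04,
                         amplitude=15e-6)
    pre = StateProfile(alpha_frac=0.25, gamma_lo_frac=0.25, gamma_hi_frac=0.20,
                       amplitude=25e-6)
    # ictal morphology is not modeled; these windows never enter training
    ictal = StateProfile(alpha_frac=0.15, gamma_lo_frac=0.35, gamma_hi_frac=0.30,
                         amplitude=75e-6)
    return {INTER_ICTAL: inter, PRE_ICTAL: pre, ICTAL: ictal, POST_ICTAL: inter}


@dataclass
class EEGSimSpec:
    """Configuration of the raw-EEG synthesizer."""

    duration: float = 86400.0
    fs: float = 256.0
    bands: BandSpec = field(default_factory=BandSpec)
    background_band: tuple[float, float] = (1.0, 8.0)
    profiles: dict[str, StateProfile] = field(default_factory=_default_profiles)
    pre_dur: float = 3600.0
    post_dur: float = 3600.0
    crossfade: float = 10.0  # seconds of smooth gain transition at state edges
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 2.0 * self.bands.max_edge:
            raise ValueError("fs must be at least twice the highest band edge")
        if INTER_ICTAL not in self.profiles or PRE_ICTAL not in self.profiles:
            raise ValueError("profiles must cover inter_ictal and pre_ictal")


def _band_noise(n: int, band: tuple[float, float], fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi) by spectral masking.

    Spectral synthesis (rather than time-domain filtering) keeps the
    carrier's energy strictly in-band, so periodogram band fractions of
    the mixed signal recover the profile targets."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    spec[~((freqs >= band[0]) & (freqs < band[1]))] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def generate_eeg(spec: EEGSimSpec, tl: SeizureTimeline) -> np.ndarray:
    """Synthesize a raw EEG record following the timeline's ictal states.

    The signal is a sum of four unit-variance band-limited noise carriers
    (background, alpha, low gamma, high gamma) under per-band gain
    envelopes.  Per state, the gain of band b is
    ``amplitude * sqrt(target_frac_b)``, so windowed periodogram fractions
    recover the targets in expectation; envelopes crossfade smoothly over
    ``spec.crossfade`` seconds at state boundaries.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    bands = [spec.background_band, spec.bands.alpha, spec.bands.gamma_lo, spec.bands.gamma_hi]

    # gain targets on a 1 s grid, smoothed, then interpolated to samples
    tick = np.arange(int(np.ceil(spec.duration)), dtype=float)
    states = label_timeline(tl, tick, pre_dur=spec.pre_dur, post_dur=spec.post_dur)
    profiles = {**_default_profiles(), **spec.profiles}
    gains = np.empty((len(bands), tick.size))
    for j, st in enumerate(states):
        p = profiles[st]
        fr = [p.background_frac, p.alpha_frac, p.gamma_lo_frac, p.gamma_hi_frac]
        gains[:, j] = p.amplitude * np.sqrt(fr)
    fade = max(int(round(spec.crossfade)), 1)
    kernel = np.hanning(fade + 2)[1:-1]
    kernel /= kernel.sum()
    if kernel.size > 1:
        pad = kernel.size // 2
        padded = np.pad(gains, ((0, 0), (pad, pad)), mode="edge")
        gains = np.apply_along_axis(lambda g: np.convolve(g, kernel, mode="same"),
                                    1, padded)[:, pad:pad + tick.size]

    t_samples = np.arange(n) / spec.fs
    signal = np.zeros(n)
    for b, band in enumerate(bands):
        env = np.interp(t_samples, tick, gains[b])
        signal += env * _band_noise(n, band, spec.fs, rng)
    return signal
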