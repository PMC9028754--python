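"""Windowing and feature extraction for single-channel EEG.

The classifier works on four features per analysis window: the signal's
peak-to-peak voltage and the fractions of spectral power in the alpha
band and in the lower and upper halves of the gamma band.  Band edges
follow conventional EEG definitions (alpha 8-13 Hz; gamma 30-100 Hz split
at 65 Hz) and are fully configurable.

Power fractions are computed from a Hann-windowed periodogram; the DC bin
is excluded from the total so electrode offsets do not dilute the
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import periodogram

__all__ = [
    "SignalWindow",
    "BandSpec",
    "FeatureVector",
    "make_windows",
    "extract_features",
    "extract_feature_table",
    "FEATURE_COLUMNS",
    "read_signal_csv",
    "write_signal_csv",
    "read_edf",
]

FEATURE_COLUMNS = ["vpp", "alpha_frac", "gamma_lo_frac", "gamma_hi_frac"]


@dataclass
class SignalWindow:
    """One analysis window of sampled signal."""

    samples: np.ndarray  # volts
    fs: float  # Hz
    t_start: float = 0.0  # seconds

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("window must be nonempty")


@dataclass(frozen=True)
class BandSpec:
    """Frequency bands for the three power-fraction features (Hz)."""

    alpha: tuple[float, float] = (8.0, 13.0)
    gamma_lo: tuple[float, float] = (30.0, 65.0)
    gamma_hi: tuple[float, float] = (65.0, 100.0)

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma_lo", "gamma_hi"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"band {name} must satisfy 0 < lo < hi, got ({lo}, {hi})")
        if self.gamma_lo[1] != self.gamma_hi[0]:
            raise ValueError("gamma_lo must end where gamma_hi begins")

    @property
    def max_edge(self) -> float:
        return max(self.alpha[1], self.gamma_lo[1], self.gamma_hi[1])


@dataclass(frozen=True)
class FeatureVector:
    """The 4-D feature vector of one window."""

    vpp: float
    alpha_frac: float
    gamma_lo_frac: float
    gamma_hi_frac: float

    def __post_init__(self) -> None:
        if self.vpp < 0:
            raise ValueError("vpp must be nonnegative")
        for name in ("alpha_frac", "gamma_lo_frac", "gamma_hi_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.vpp, self.alpha_frac, self.gamma_lo_frac, self.gamma_hi_frac])


def make_windows(signal: Sequence[float], fs: float, win_len: float = 4.0,
                 stride: float = 2.0) -> list[SignalWindow]:
    """Slice a signal into half-open windows [t, t + win_len).

    The trailing partial window is dropped; a signal shorter than one
    window yields an empty list.
    """
    if win_len <= 0 or stride <= 0:
        raise ValueError("win_len and stride must be positive")
    signal = np.asarray(signal, dtype=float)
    n_win = int(round(win_len * fs))
    n_stride = int(round(stride * fs))
    windows = []
    start = 0
    while start + n_win <= signal.size:
        windows.append(SignalWindow(samples=signal[start:start + n_win], fs=fs,
                                    t_start=start / fs))
        start += n_stride
    return windows


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (freqs >= band[0]) & (freqs < band[1])
    return float(psd[mask].sum())


def extract_features(w: SignalWindow, bands: BandSpec | None = None) -> FeatureVector:
    """Compute the 4-D feature vector of one window.

    Band fractions are ratios of periodogram power in-band to total power
    over (0, fs/2]; an all-zero (or constant) window has zero total power
    and its fractions are defined as 0.
    """
    bands = bands or BandSpec()
    if w.fs < 2.0 * bands.max_edge:
        raise ValueError(
            f"sampling rate {w.fs} Hz cannot resolve the {bands.max_edge} Hz band edge"
        )
    vpp = float(w.samples.max() - w.samples.min())
    freqs, psd = periodogram(w.samples, fs=w.fs, window="hann", detrend=False)
    nonzero = freqs > 0  # DC excluded for electrode-offset robustness
    total = float(psd[nonzero].sum())
    if total <= 0.0 or vpp == 0.0:  # constant window: zero AC energy up to roundoff
        return FeatureVector(vpp=vpp, alpha_frac=0.0, gamma_lo_frac=0.0, gamma_hi_frac=0.0)
    psd = np.where(nonzero, psd, 0.0)
    return FeatureVector(
        vpp=vpp,
        alpha_frac=_band_power(freqs, psd, bands.alpha) / total,
        gamma_lo_frac=_band_power(freqs, psd, bands.gamma_lo) / total,
        gamma_hi_frac=_band_power(freqs, psd, bands.gamma_hi) / total,
    )


def extract_feature_table(signal: Sequence[float], fs: float, win_len: float = 4.0,
                          stride: float = 2.0, bands: BandSpec | None = None) -> pd.DataFrame:
    """Window a signal and extract features; one row per window."""
    rows = []
    for w in make_windows(signal, fs, win_len, stride):
        fv = extract_features(w, bands)
        rows.append((w.t_start, fv.vpp, fv.alpha_frac, fv.gamma_lo_frac, fv.gamma_hi_frac))
    return pd.DataFrame(rows, columns=["t_start"] + FEATURE_COLUMNS)


# ---------------------------------------------------------------------------
# I/O


def read_signal_csv(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a (time, value) CSV; returns (samples, fs).

    The sampling rate is inferred from the median time step.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("signal CSV needs (time, value) columns")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValueError("time column must be strictly increasing")
    return x, 1.0 / dt


def write_signal_csv(path: str | Path, signal: np.ndarray, fs: float) -> None:
    t = np.arange(len(signal)) / fs
    pd.DataFrame({"time_s": t, "value_v": signal}).to_csv(path, index=False)


def read_edf(path: str | Path, channel: str | int = 0) -> tuple[np.ndarray, float]:
    """Read one channel from an EDF file (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF ingestion requires mne (pip install gmmwake[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if isinstance(channel, int):
        channel = raw.ch_names[channel]
    data = raw.get_data(picks=[channel])[0]
    return np.asarray(data, dtype=float), float(raw.info["sfreq"])
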