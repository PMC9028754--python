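"""Behavioral model of the analog GMM classifier.

The hardware realizes each univariate Gaussian with a subthreshold bump
circuit whose output current traces a bell curve of the input voltage:
the mean is set by a reference voltage Vr, the width by a control voltage
Vc, and the height by a bias current Ibias.  Cascading N bumps (each
stage's output current biases the next) multiplies their curves, giving a
diagonal-covariance multivariate Gaussian; current mirrors sum the K
cluster currents of a class, and a winner-take-all (WTA) stage performs
the argmax across classes.

Everything here is an equation-level, steady-state model: currents are
real numbers in amperes, voltages in volts, and no transistor-level or
transient behavior is represented.  The bump transfer law is the classic
subthreshold differential-pair response,

    I(v) = Ibias * sech^2((v - Vr) / (2 * n * U_T * w(Vc))),

with slope factor ``n``, thermal voltage ``U_T``, and a monotone width
function ``w(Vc) = exp((Vc - c0) / c1)``.  A sech^2 curve is Gaussian-like
(its best-fit Gaussian over +-4 effective sigma has R^2 > 0.99), so the
mapped classifier tracks the ideal one away from decision boundaries.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .gmm import GMMClassifier

__all__ = [
    "DeviceModel",
    "BumpParams",
    "FeatureScaler",
    "WidthCalibration",
    "AnalogClassifierConfig",
    "MismatchSpec",
    "bump_current",
    "bump_shape",
    "multivariate_bump",
    "class_current",
    "wta",
    "calibrate_width",
    "map_gmm_to_analog",
    "classify_analog",
    "classify_analog_batch",
    "apply_mismatch",
    "monte_carlo_eval",
]

#: losers of the WTA must sit below this current to count as logical zero
WTA_LOGICAL_ZERO = 100e-12


@dataclass(frozen=True)
class DeviceModel:
    """Device constants shared by every bump in the classifier.

    thermal_voltage : kT/q at room temperature, volts.
    subthreshold_slope_factor : dimensionless gate-coupling factor in (0, 1].
    supply_pos / supply_neg : rails, volts (symmetric 0.6 V supply).
    width_c0, width_c1 : coefficients of the width law w(Vc)=exp((Vc-c0)/c1).
    leakage_floor : additive off-current per bump, amperes.
    """

    thermal_voltage: float = 0.02585
    subthreshold_slope_factor: float = 0.7
    supply_pos: float = 0.3
    supply_neg: float = -0.3
    width_c0: float = 0.0
    width_c1: float = 0.3
    leakage_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.thermal_voltage <= 0:
            raise ValueError("thermal_voltage must be positive")
        if not 0 < self.subthreshold_slope_factor <= 1:
            raise ValueError("slope factor must lie in (0, 1]")
        if self.supply_pos <= self.supply_neg:
            raise ValueError("supply_pos must exceed supply_neg")

    def width(self, v_c: float | np.ndarray) -> float | np.ndarray:
        """Monotone width multiplier w(Vc); strictly positive."""
        with np.errstate(over="ignore"):
            w = np.exp((np.asarray(v_c, dtype=float) - self.width_c0) / self.width_c1)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("width function produced a non-positive or non-finite value")
        return w if np.ndim(v_c) else float(w)


@dataclass
class BumpParams:
    """Control parameters of one univariate bump stage.

    ``i_bias`` is meaningful only on a cluster's first stage (it sets the
    cluster height); ``width_gain`` is a multiplicative mismatch term on
    the effective width, nominally 1.
    """

    v_r: float
    v_c: float
    i_bias: float = 0.0
    width_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.i_bias < 0:
            raise ValueError("i_bias must be nonnegative")


@dataclass
class FeatureScaler:
    """Per-dimension affine map from feature units to input volts."""

    gain: np.ndarray  # volts per feature unit
    offset: np.ndarray  # volts

    def __post_init__(self) -> None:
        self.gain = np.atleast_1d(np.asarray(self.gain, dtype=float))
        self.offset = np.atleast_1d(np.asarray(self.offset, dtype=float))
        if self.gain.shape != self.offset.shape:
            raise ValueError("gain and offset must have equal length")
        if np.any(self.gain == 0):
            raise ValueError("scaler must be invertible: zero gain")

    @classmethod
    def from_data(
        cls,
        X: np.ndarray,
        v_lo: float = -0.15,
        v_hi: float = 0.15,
        pct_lo: float = 1.0,
        pct_hi: float = 99.0,
    ) -> "FeatureScaler":
        """Map the [pct_lo, pct_hi] percentile range of each feature onto
        [v_lo, v_hi], leaving headroom to the supply rails."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo = np.percentile(X, pct_lo, axis=0)
        hi = np.percentile(X, pct_hi, axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)  # guard constant features
        gain = (v_hi - v_lo) / span
        offset = v_lo - gain * lo
        return cls(gain=gain, offset=offset)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.gain + self.offset

    def inverse(self, V: np.ndarray) -> np.ndarray:
        return (np.asarray(V, dtype=float) - self.offset) / self.gain


@dataclass
class MismatchSpec:
    """Per-device random variation model for the Monte-Carlo analysis.

    sigma_vr_offset : std of an additive Vr offset per bump, volts.
    sigma_width_gain : relative std of the effective-width gain per bump.
    sigma_current_gain : relative std of the bias-current gain per cluster.
    """

    sigma_vr_offset: float = 2e-3
    sigma_width_gain: float = 0.02
    sigma_current_gain: float = 0.02
    n_runs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_vr_offset, self.sigma_width_gain, self.sigma_current_gain) < 0:
            raise ValueError("mismatch sigmas must be nonnegative")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


# ---------------------------------------------------------------------------
# bump primitives


def _sech2(u: np.ndarray) -> np.ndarray:
    return 1.0 / np.cosh(u) ** 2


def bump_shape(v_in, p: BumpParams, d: DeviceModel):
    """Unit-peak bump transfer: sech^2 of the normalized input offset."""
    denom = 2.0 * d.subthreshold_slope_factor * d.thermal_voltage * d.width(p.v_c) * p.width_gain
    return _sech2((np.asarray(v_in, dtype=float) - p.v_r) / denom)


def bump_current(v_in, p: BumpParams, d: DeviceModel):
    """Output current of a single bump stage, amperes.

    Peaks at ``i_bias`` (plus the leakage floor) when ``v_in == v_r`` and is
    even-symmetric about the peak.
    """
    return p.i_bias * bump_shape(v_in, p, d) + d.leakage_floor


def multivariate_bump(v_in: Sequence[float], cluster: Sequence[BumpParams], d: DeviceModel) -> float:
    """Output current of a cascade of N bump stages, amperes.

    Only the first stage's ``i_bias`` matters; each later stage is biased
    by its predecessor's output, so the result is the first bias current
    times the product of the unit-peak shapes.
    """
    if len(cluster) == 0:
        raise ValueError("cluster must contain at least one bump")
    v_in = np.asarray(v_in, dtype=float)
    if v_in.shape != (len(cluster),):
        raise ValueError(f"expected {len(cluster)} input voltages, got shape {v_in.shape}")
    out = cluster[0].i_bias
    for v, p in zip(v_in, cluster):
        out = out * bump_shape(v, p, d)
    return float(out + d.leakage_floor)


def class_current(v_in: Sequence[float], clusters: Sequence[Sequence[BumpParams]],
                  d: DeviceModel) -> float:
    """Summed cluster currents of one class (mirror addition), amperes."""
    return float(sum(multivariate_bump(v_in, cl, d) for cl in clusters))


def wta(currents: Sequence[float], wta_bias: float,
        soft_gain: float | None = None) -> tuple[int, np.ndarray]:
    """Winner-take-all: the analog argmax.

    Returns the winner index (ties broken toward the lowest index) and the
    output currents: the winner carries ``wta_bias`` (logical one), every
    loser is below 100 pA (logical zero; exactly 0 in the default ideal
    mode).  ``soft_gain`` enables a finite-gain mode in which losers leak
    a residual current shrinking with their distance from the winner.
    """
    currents = np.asarray(currents, dtype=float)
    if currents.size == 0:
        raise ValueError("wta needs at least one input current")
    if np.any(currents < 0):
        raise ValueError("input currents must be nonnegative")
    winner = int(np.argmax(currents))
    out = np.zeros_like(currents)
    out[winner] = wta_bias
    if soft_gain is not None:
        peak = currents[winner]
        if peak > 0:
            ratio = currents / peak
            resid = wta_bias * ratio**soft_gain
            resid = np.minimum(resid, 0.99 * WTA_LOGICAL_ZERO)
            mask = np.ones_like(out, dtype=bool)
            mask[winner] = False
            out[mask] = resid[mask]
    return winner, out


# ---------------------------------------------------------------------------
# width calibration


@dataclass
class WidthCalibration:
    """Tabulated map between the width-control voltage Vc and the effective
    Gaussian sigma (volts) of the bump curve."""

    vc_grid: np.ndarray
    sigma_grid: np.ndarray

    def __post_init__(self) -> None:
        self.vc_grid = np.asarray(self.vc_grid, dtype=float)
        self.sigma_grid = np.asarray(self.sigma_grid, dtype=float)

    def sigma_of_vc(self, v_c: float) -> float:
        return float(np.interp(v_c, self.vc_grid, self.sigma_grid))

    def vc_of_sigma(self, sigma: float) -> float:
        """Inverse map; out-of-range requests are clamped with a warning."""
        if sigma < self.sigma_grid[0] or sigma > self.sigma_grid[-1]:
            warnings.warn(
                f"sigma={sigma:.3g} V outside calibrated range "
                f"[{self.sigma_grid[0]:.3g}, {self.sigma_grid[-1]:.3g}] V; clamping",
                stacklevel=2,
            )
            sigma = float(np.clip(sigma, self.sigma_grid[0], self.sigma_grid[-1]))
        return float(np.interp(sigma, self.sigma_grid, self.vc_grid))


def _fit_gaussian_sigma(v: np.ndarray, i: np.ndarray) -> tuple[float, float]:
    """Least-squares Gaussian fit; returns (amplitude, sigma)."""

    def g(x, a, s):
        return a * np.exp(-(x**2) / (2.0 * s**2))

    s0 = float(np.sqrt(np.sum(i * v**2) / np.sum(i)))
    popt, _ = curve_fit(g, v, i, p0=[float(i.max()), s0])
    return float(popt[0]), abs(float(popt[1]))


def effective_sigma(p: BumpParams, d: DeviceModel, n_points: int = 801) -> float:
    """Effective Gaussian sigma (volts) of a bump, by least-squares fit
    over +-4 sigma of the curve (two fitting passes to set the span)."""
    half = 2.0 * d.subthreshold_slope_factor * d.thermal_voltage * d.width(p.v_c) * p.width_gain
    v = np.linspace(-8 * half, 8 * half, n_points)
    y = bump_shape(v + p.v_r, p, d)
    _, s = _fit_gaussian_sigma(v, y)
    v = np.linspace(-4 * s, 4 * s, n_points)
    y = bump_shape(v + p.v_r, p, d)
    _, s = _fit_gaussian_sigma(v, y)
    return s


def calibrate_width(d: DeviceModel, vc_grid: Sequence[float] | None = None) -> WidthCalibration:
    """Tabulate the Vc -> effective-sigma map on a grid of control voltages.

    Raises a calibration error if the fitted widths are not strictly
    increasing on the grid (the interpolated inverse would be ill-posed).
    """
    if vc_grid is None:
        vc_grid = np.linspace(d.supply_neg, d.supply_pos, 25)
    vc_grid = np.asarray(vc_grid, dtype=float)
    if np.any(vc_grid < d.supply_neg) or np.any(vc_grid > d.supply_pos):
        raise ValueError("vc_grid must lie within the supply rails")
    sigmas = np.array([effective_sigma(BumpParams(v_r=0.0, v_c=vc, i_bias=1.0), d)
                       for vc in vc_grid])
    if not np.all(np.diff(sigmas) > 0):
        raise RuntimeError(f"calibration failed: non-monotone widths on grid {vc_grid!r}")
    return WidthCalibration(vc_grid=vc_grid, sigma_grid=sigmas)


# ---------------------------------------------------------------------------
# configuration, mapping, inference


@dataclass
class AnalogClassifierConfig:
    """Full parameterization of the analog classifier.

    ``classes`` is a rectangular C x K x N nest of bump parameters;
    ``scaler`` maps feature units to input volts; ``wta_bias`` sets the
    logical-one output current.
    """

    classes: list[list[list[BumpParams]]]
    scaler: FeatureScaler
    device: DeviceModel = field(default_factory=DeviceModel)
    wta_bias: float = 12e-9
    tied_weights: bool = False

    def __post_init__(self) -> None:
        if len(self.classes) < 1:
            raise ValueError("config needs at least one class")
        ks = {len(cls_) for cls_ in self.classes}
        ns = {len(cl) for cls_ in self.classes for cl in cls_}
        if len(ks) != 1 or len(ns) != 1:
            raise ValueError("config must be rectangular (C x K x N)")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_clusters(self) -> int:
        return len(self.classes[0])

    @property
    def n_dims(self) -> int:
        return len(self.classes[0][0])

    def to_dict(self) -> dict:
        return {
            "wta_bias": self.wta_bias,
            "tied_weights": self.tied_weights,
            "device": asdict(self.device),
            "scaler": {"gain": self.scaler.gain.tolist(), "offset": self.scaler.offset.tolist()},
            "classes": [
                [[asdict(p) for p in cl] for cl in cls_] for cls_ in self.classes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalogClassifierConfig":
        return cls(
            classes=[
                [[BumpParams(**p) for p in cl] for cl in cls_] for cls_ in d["classes"]
            ],
            scaler=FeatureScaler(gain=np.asarray(d["scaler"]["gain"]),
                                 offset=np.asarray(d["scaler"]["offset"])),
            device=DeviceModel(**d["device"]),
            wta_bias=d["wta_bias"],
            tied_weights=d.get("tied_weights", False),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AnalogClassifierConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def map_gmm_to_analog(
    clf: GMMClassifier,
    device: DeviceModel | None = None,
    scaler: FeatureScaler | None = None,
    calibration: WidthCalibration | None = None,
    full_scale: float = 12e-9,
    tied_weights: bool = False,
    wta_bias: float | None = None,
) -> AnalogClassifierConfig:
    """Translate a trained software GMM into analog control parameters.

    Per dimension, the component mean maps to Vr through the feature
    scaler and the component sigma (in volts) maps to Vc through the
    inverse width calibration.  The cluster bias current encodes the
    mixture weight times the Gaussian normalization constants, so the
    summed class current stays proportional to the class likelihood; the
    currents are then normalized so the largest cluster bias equals
    ``full_scale`` (default 12 nA).  ``tied_weights`` forces equal bias
    currents within each class, mirroring hardware with one bias source
    per class.
    """
    device = device or DeviceModel()
    if scaler is None:
        raise ValueError("a feature scaler is required (build one with FeatureScaler.from_data)")
    calibration = calibration or calibrate_width(device)

    raw_bias = np.empty((clf.n_classes, clf.n_clusters))
    classes: list[list[list[BumpParams]]] = []
    for c, g in enumerate(clf.classes):
        clusters: list[list[BumpParams]] = []
        for k, comp in enumerate(g.components):
            v_r = scaler.transform(comp.mean)
            sigma_v = np.abs(scaler.gain) * np.sqrt(comp.var)
            bumps = []
            norm = 1.0
            for n in range(clf.n_dims):
                v_c = calibration.vc_of_sigma(float(sigma_v[n]))
                sigma_real = calibration.sigma_of_vc(v_c)
                norm *= 1.0 / (np.sqrt(2.0 * np.pi) * sigma_real)
                bumps.append(BumpParams(v_r=float(v_r[n]), v_c=v_c))
            raw_bias[c, k] = comp.weight * norm
            clusters.append(bumps)
        classes.append(clusters)

    if tied_weights:
        raw_bias = np.repeat(raw_bias.mean(axis=1, keepdims=True), clf.n_clusters, axis=1)
    bias = raw_bias * (full_scale / raw_bias.max())
    for c in range(clf.n_classes):
        for k in range(clf.n_clusters):
            classes[c][k][0].i_bias = float(bias[c, k])

    return AnalogClassifierConfig(
        classes=classes,
        scaler=scaler,
        device=device,
        wta_bias=full_scale if wta_bias is None else wta_bias,
        tied_weights=tied_weights,
    )


def _features_to_volts(X: np.ndarray, cfg: AnalogClassifierConfig) -> np.ndarray:
    V = cfg.scaler.transform(X)
    lo, hi = cfg.device.supply_neg, cfg.device.supply_pos
    if np.any(V < lo) or np.any(V > hi):
        warnings.warn("input outside the supply rails; clamping", stacklevel=3)
        V = np.clip(V, lo, hi)
    return V


def class_currents_batch(X: np.ndarray, cfg: AnalogClassifierConfig) -> np.ndarray:
    """Class output currents for each row of the feature matrix, shape (n, C)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = _features_to_volts(X, cfg)
    d = cfg.device
    out = np.zeros((X.shape[0], cfg.n_classes))
    for c, clusters in enumerate(cfg.classes):
        for cl in clusters:
            cur = np.full(X.shape[0], cl[0].i_bias)
            for n, p in enumerate(cl):
                denom = (2.0 * d.subthreshold_slope_factor * d.thermal_voltage
                         * d.width(p.v_c) * p.width_gain)
                cur = cur * _sech2((V[:, n] - p.v_r) / denom)
            out[:, c] += cur + d.leakage_floor
    return out


def classify_analog(x: Sequence[float], cfg: AnalogClassifierConfig) -> int:
    """Classify one feature vector through the analog signal chain:
    feature scaling, per-class current summation, WTA argmax."""
    currents = class_currents_batch(np.asarray(x, dtype=float)[None, :], cfg)[0]
    winner, _ = wta(currents, cfg.wta_bias)
    return winner


def classify_analog_batch(X: np.ndarray, cfg: AnalogClassifierConfig) -> np.ndarray:
    """Vectorized :func:`classify_analog` over rows of ``X``."""
    currents = class_currents_batch(X, cfg)
    return np.argmax(currents, axis=1)


# ---------------------------------------------------------------------------
# mismatch Monte-Carlo


def apply_mismatch(cfg: AnalogClassifierConfig, spec: MismatchSpec,
                   run_index: int) -> AnalogClassifierConfig:
    """One Monte-Carlo draw: independent Gaussian perturbations per bump.

    Vr gets an additive offset, the effective width and the bias current
    get multiplicative gain errors.  Deterministic given (seed, run_index).
    """
    rng = np.random.default_rng([spec.seed, run_index])
    out = copy.deepcopy(cfg)
    for clusters in out.classes:
        for cl in clusters:
            for p in cl:
                p.v_r += rng.normal(0.0, spec.sigma_vr_offset)
                p.width_gain *= 1.0 + rng.normal(0.0, spec.sigma_width_gain)
                if p.i_bias > 0:
                    p.i_bias *= max(1.0 + rng.normal(0.0, spec.sigma_current_gain), 0.0)
    return out


def monte_carlo_eval(
    cfg: AnalogClassifierConfig,
    spec: MismatchSpec,
    X: np.ndarray,
    y: np.ndarray,
    negative_class: int = 1,
) -> tuple[list[float], float, float]:
    """Specificity distribution under device mismatch.

    Runs ``spec.n_runs`` independent perturbations of the configuration,
    classifies the labeled windows under each, and measures per-run
    specificity: the fraction of true inter-ictal (negative-class) windows
    classified as negative.  Returns (per-run list, mean, std).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty evaluation data")
    neg = y == negative_class
    if not neg.any():
        raise ValueError("no negative-class windows in the evaluation data")
    specs = []
    for r in range(spec.n_runs):
        pred = classify_analog_batch(X, apply_mismatch(cfg, spec, r))
        specs.append(float(np.mean(pred[neg] == negative_class)))
    return specs, float(np.mean(specs)), float(np.std(specs))
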