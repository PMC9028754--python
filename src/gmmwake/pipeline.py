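"""High-level training and evaluation flows tying the modules together.

Class convention: class index 0 is pre-ictal (the alarm-raising class),
class index 1 is inter-ictal.  Training uses pre-ictal and inter-ictal
windows only; ictal and post-ictal windows never enter training and are
excluded from the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analog as an
from . import evaluate as ev
from . import gmm
from .features import FEATURE_COLUMNS

__all__ = [
    "CLASS_LABELS",
    "PowerConstants",
    "train_classifier",
    "train_test_split_windows",
    "predict_windows",
    "evaluate_windows",
    "accounting_report",
]

#: class order of every trained classifier: index 0 raises the alarm
CLASS_LABELS = [ev.PRE_ICTAL, ev.INTER_ICTAL]


@dataclass(frozen=True)
class PowerConstants:
    """Hardware power/throughput constants (configuration inputs, never
    computed by this package).

    Defaults: 180 nW analog classifier at 166 K classifications/s, with a
    3.07 uW digital back-end representative of embedded seizure-prediction
    engines.
    """

    p_analog: float = 180e-9  # watts
    p_digital: float = 3.07e-6  # watts
    classification_rate: float = 166e3  # 1/s


def train_classifier(
    features: pd.DataFrame,
    n_clusters: int = 2,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> gmm.GMMClassifier:
    """Fit one diagonal-covariance GMM per class on a labeled feature table.

    ``features`` needs the four feature columns plus a ``state`` column;
    only pre-ictal and inter-ictal rows are used.
    """
    classes = []
    for label in CLASS_LABELS:
        sub = features.loc[features["state"] == label, FEATURE_COLUMNS]
        if len(sub) < n_clusters:
            raise ValueError(f"not enough {label} windows ({len(sub)}) for K={n_clusters}")
        classes.append(
            gmm.fit_em(sub.to_numpy(), n_clusters, seed=seed, tol=tol,
                       max_iter=max_iter, label=label)
        )
    return gmm.GMMClassifier(classes=classes)


def train_test_split_windows(features: pd.DataFrame, train_frac: float = 0.5,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random window-level split, stratified by state."""
    rng = np.random.default_rng(seed)
    train_mask = np.zeros(len(features), dtype=bool)
    for state in features["state"].unique():
        idx = np.flatnonzero((features["state"] == state).to_numpy())
        picked = rng.choice(idx, size=int(round(train_frac * idx.size)), replace=False)
        train_mask[picked] = True
    return features[train_mask], features[~train_mask]


def predict_windows(
    features: pd.DataFrame,
    clf: gmm.GMMClassifier,
    mode: str = "ideal",
    analog_cfg: an.AnalogClassifierConfig | None = None,
) -> np.ndarray:
    """Per-window class predictions in the fixed class order."""
    X = features[FEATURE_COLUMNS].to_numpy()
    if mode == "ideal":
        return gmm.classify_batch(X, clf)
    if mode == "analog":
        if analog_cfg is None:
            raise ValueError("analog mode needs an AnalogClassifierConfig")
        return an.classify_analog_batch(X, analog_cfg)
    raise ValueError(f"unknown mode {mode!r} (expected 'ideal' or 'analog')")


def evaluate_windows(
    features: pd.DataFrame,
    predictions: np.ndarray,
    tl: ev.SeizureTimeline,
    pre_dur: float = 3600.0,
    post_dur: float = 3600.0,
    smoothing: int = 1,
    power: PowerConstants | None = None,
) -> ev.EvalReport:
    """Alarm-based evaluation of per-window predictions on a timeline."""
    alarms = ev.alarms_from_predictions(predictions, positive_class=0,
                                        smoothing=smoothing)
    power = power or PowerConstants()
    return ev.evaluate_alarms(
        alarms,
        features["t_start"].to_numpy(),
        tl,
        pre_dur=pre_dur,
        post_dur=post_dur,
        p_analog=power.p_analog,
        p_digital=power.p_digital,
    )


def accounting_report(arch: gmm.ArchitectureSpec,
                      power: PowerConstants | None = None) -> dict:
    """Parameter, operation, and energy accounting for one architecture."""
    power = power or PowerConstants()
    n_params = gmm.count_parameters(arch)
    n_ops = gmm.count_operations(arch)
    e_classification = power.p_analog / power.classification_rate
    return {
        "n_classes": arch.n_classes,
        "n_clusters": arch.n_clusters,
        "n_dims": arch.n_dims,
        "n_parameters": n_params,
        "n_operations": n_ops,
        "power_analog_w": power.p_analog,
        "classification_rate_hz": power.classification_rate,
        "energy_per_classification_j": e_classification,
        "energy_per_operation_j": e_classification / n_ops,
    }
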