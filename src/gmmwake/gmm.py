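"""Ideal (software) Gaussian-mixture-model classifier.

This module implements the mathematical core of the wake-up classifier:
diagonal-covariance Gaussian mixtures per class, expectation-maximization
training, maximum-likelihood (argmax) classification, and the
parameter/operation accounting used to size the analog realization.

A classifier holds one mixture per class; all mixtures share the same
cluster count ``K``.  Classification assigns an input vector to the class
whose mixture density is highest, with ties broken toward the lowest
class index.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "GaussianComponent",
    "ClassGMM",
    "GMMClassifier",
    "ArchitectureSpec",
    "gaussian_pdf",
    "component_pdf",
    "mixture_pdf",
    "log_mixture_pdf",
    "fit_em",
    "classify",
    "classify_batch",
    "count_parameters",
    "count_operations",
    "save_classifier",
    "load_classifier",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class GaussianComponent:
    """One diagonal-covariance Gaussian component of a mixture.

    Parameters
    ----------
    mean : array of shape (N,)
        Component mean, in feature units.
    var : array of shape (N,)
        Diagonal of the covariance matrix, strictly positive,
        in feature units squared.
    weight : float
        Mixing weight in [0, 1].
    """

    mean: np.ndarray
    var: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.var = np.atleast_1d(np.asarray(self.var, dtype=float))
        if self.mean.shape != self.var.shape:
            raise ValueError(
                f"mean and var must have equal length, got {self.mean.shape} vs {self.var.shape}"
            )
        if not np.all(self.var > 0):
            raise ValueError("variances must be strictly positive")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must lie in [0, 1], got {self.weight}")

    @property
    def n_dims(self) -> int:
        return self.mean.size


@dataclass
class ClassGMM:
    """Gaussian mixture modelling the feature density of one class."""

    components: list[GaussianComponent]
    label: object = None

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValueError("a mixture needs at least one component")
        dims = {c.n_dims for c in self.components}
        if len(dims) != 1:
            raise ValueError("all components must share the same dimensionality")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total!r}")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_dims(self) -> int:
        return self.components[0].n_dims

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        """Stacked component means, shape (K, N)."""
        return np.stack([c.mean for c in self.components])

    @property
    def variances(self) -> np.ndarray:
        """Stacked component variances, shape (K, N)."""
        return np.stack([c.var for c in self.components])


@dataclass
class GMMClassifier:
    """A bank of per-class mixtures classified by maximum likelihood."""

    classes: list[ClassGMM]
    n_dims: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a classifier needs at least two classes")
        ks = {g.n_components for g in self.classes}
        if len(ks) != 1:
            raise ValueError("all class mixtures must share the same cluster count K")
        dims = {g.n_dims for g in self.classes}
        if len(dims) != 1:
            raise ValueError("all class mixtures must share the same dimensionality")
        dim = dims.pop()
        if self.n_dims == 0:
            self.n_dims = dim
        elif self.n_dims != dim:
            raise ValueError(f"n_dims={self.n_dims} does not match components ({dim})")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_clusters(self) -> int:
        return self.classes[0].n_components

    @property
    def architecture(self) -> "ArchitectureSpec":
        return ArchitectureSpec(self.n_classes, self.n_clusters, self.n_dims)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Size of the classifier: C classes, K clusters per class, N dims."""

    n_classes: int
    n_clusters: int
    n_dims: int

    def __post_init__(self) -> None:
        for name in ("n_classes", "n_clusters", "n_dims"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# densities


def gaussian_pdf(x: float, mean: float, var: float) -> float:
    """Univariate normal density at ``x``.

    Raises
    ------
    ValueError
        If ``var`` is not strictly positive.
    """
    if var <= 0:
        raise ValueError(f"variance must be positive, got {var}")
    z = (x - mean) ** 2 / var
    return math.exp(-0.5 * (z + _LOG_2PI + math.log(var)))


def component_pdf(x: Sequence[float], comp: GaussianComponent) -> float:
    """Diagonal-covariance multivariate normal density: the product of the
    per-dimension univariate densities."""
    x = np.asarray(x, dtype=float)
    if x.shape != comp.mean.shape:
        raise ValueError(f"dimension mismatch: x has shape {x.shape}, component is {comp.mean.shape}")
    return float(np.exp(_log_component_pdf(x, comp)))


def _log_component_pdf(x: np.ndarray, comp: GaussianComponent) -> float:
    z = (x - comp.mean) ** 2 / comp.var
    return float(-0.5 * np.sum(z + _LOG_2PI + np.log(comp.var)))


def mixture_pdf(x: Sequence[float], gmm: ClassGMM) -> float:
    """Mixture likelihood: weighted sum of the component densities."""
    x = np.asarray(x, dtype=float)
    return float(sum(c.weight * component_pdf(x, c) for c in gmm.components))


def log_mixture_pdf(x: Sequence[float], gmm: ClassGMM) -> float:
    """Log mixture likelihood, evaluated stably via log-sum-exp."""
    x = np.asarray(x, dtype=float)
    terms = np.array(
        [math.log(c.weight) + _log_component_pdf(x, c) if c.weight > 0 else -np.inf
         for c in gmm.components]
    )
    return float(logsumexp(terms))


def _log_prob_matrix(data: np.ndarray, means: np.ndarray, variances: np.ndarray,
                     weights: np.ndarray) -> np.ndarray:
    """Weighted per-component log densities; shape (n_samples, K)."""
    # (n, K) via broadcasting over the feature axis
    z = (data[:, None, :] - means[None, :, :]) ** 2 / variances[None, :, :]
    log_comp = -0.5 * np.sum(z + _LOG_2PI + np.log(variances)[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        return log_comp + np.log(weights)[None, :]


# ---------------------------------------------------------------------------
# EM training


def fit_em(
    data: Sequence[Sequence[float]],
    n_clusters: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    var_floor: float = 1e-6,
    label: object = None,
    return_trace: bool = False,
) -> ClassGMM | tuple[ClassGMM, list[float]]:
    """Fit a diagonal-covariance Gaussian mixture by expectation-maximization.

    Initialization is a k-means partition of the data with a fixed seed,
    so the fit is deterministic given ``seed``.  Variances are floored to
    prevent singular components: the floor is ``var_floor`` times the
    per-dimension variance of the full data set (so features on volt and
    on dimensionless scales are floored proportionately), with a tiny
    absolute fallback for degenerate all-identical data.  Convergence is
    declared when the relative change of the mean log-likelihood drops
    below ``tol``.

    Parameters
    ----------
    data : array-like of shape (n_samples, n_dims)
    n_clusters : int
        Component count K; must not exceed the number of samples.
    return_trace : bool
        If True, also return the per-iteration mean log-likelihood trace
        (non-decreasing, up to the convergence tolerance).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = data.shape
    if n == 0:
        raise ValueError("data must be nonempty")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds sample count {n}")

    # scale-aware floor: relative to each dimension's overall spread
    floor = np.maximum(var_floor * data.var(axis=0), 1e-18)

    if n_clusters == 1:
        # closed-form maximum likelihood: sample mean, biased sample variance
        mean = data.mean(axis=0)
        var = np.maximum(data.var(axis=0), floor)
        comp = GaussianComponent(mean=mean, var=var, weight=1.0)
        gmm = ClassGMM(components=[comp], label=label)
        if return_trace:
            ll = _log_prob_matrix(data, mean[None], var[None], np.array([1.0]))
            return gmm, [float(logsumexp(ll, axis=1).mean())]
        return gmm

    km = KMeans(n_clusters=n_clusters, n_init=1, random_state=seed).fit(data)
    assign = km.labels_
    means = km.cluster_centers_.copy()
    variances = np.empty_like(means)
    weights = np.empty(n_clusters)
    for k in range(n_clusters):
        mask = assign == k
        weights[k] = max(mask.sum(), 1) / n
        if mask.any():
            variances[k] = data[mask].var(axis=0)
        else:
            variances[k] = data.var(axis=0)
    weights /= weights.sum()
    variances = np.maximum(variances, floor)

    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step
        log_wp = _log_prob_matrix(data, means, variances, weights)
        log_norm = logsumexp(log_wp, axis=1)
        ll = float(log_norm.mean())
        trace.append(ll)
        resp = np.exp(log_wp - log_norm[:, None])

        # M step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ data) / nk[:, None]
        sq = resp.T @ (data**2) / nk[:, None]
        variances = np.maximum(sq - means**2, floor)

        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(abs(prev_ll), 1.0):
            break
        prev_ll = ll

    weights = weights / weights.sum()
    comps = [
        GaussianComponent(mean=means[k], var=variances[k], weight=float(weights[k]))
        for k in range(n_clusters)
    ]
    gmm = ClassGMM(components=comps, label=label)
    return (gmm, trace) if return_trace else gmm


# ---------------------------------------------------------------------------
# classification


def classify(x: Sequence[float], clf: GMMClassifier) -> int:
    """Index of the class whose mixture likelihood is highest at ``x``.

    Ties are broken toward the lowest class index.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (clf.n_dims,):
        raise ValueError(f"expected a vector of length {clf.n_dims}, got shape {x.shape}")
    scores = [log_mixture_pdf(x, g) for g in clf.classes]
    return int(np.argmax(scores))


def classify_batch(X: Sequence[Sequence[float]], clf: GMMClassifier) -> np.ndarray:
    """Vectorized :func:`classify` over the rows of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != clf.n_dims:
        raise ValueError(f"expected {clf.n_dims} columns, got {X.shape[1]}")
    scores = np.column_stack(
        [
            logsumexp(_log_prob_matrix(X, g.means, g.variances, g.weights), axis=1)
            for g in clf.classes
        ]
    )
    return np.argmax(scores, axis=1)


# ---------------------------------------------------------------------------
# architecture accounting


def count_parameters(arch: ArchitectureSpec) -> int:
    """Number of control parameters of the analog realization.

    Each univariate bump needs one mean-control voltage (Vr) and one
    width-control voltage (Vc): ``C*K*N`` of each.  One bias current per
    class sets the height scale: ``C`` in total.  For the reference
    2-class, 2-cluster, 4-D architecture this gives 34.
    """
    c, k, n = arch.n_classes, arch.n_clusters, arch.n_dims
    return 2 * c * k * n + c


def count_operations(arch: ArchitectureSpec) -> int:
    """Scalar operations per classification.

    Convention: a univariate Gaussian evaluation costs 8 scalar operations
    (difference, square, scale by the precomputed inverse variance, halve,
    negate, exponentiate, scale by the precomputed normalizer, multiply
    into the running product); summing cluster likelihoods costs K-1
    additions per class; the argmax costs C-1 comparisons.  For the
    reference 2-class, 2-cluster, 4-D architecture this gives 131.
    """
    c, k, n = arch.n_classes, arch.n_clusters, arch.n_dims
    return 8 * c * k * n + c * (k - 1) + (c - 1)


# ---------------------------------------------------------------------------
# serialization


def classifier_to_dict(clf: GMMClassifier) -> dict:
    return {
        "n_classes": clf.n_classes,
        "n_clusters": clf.n_clusters,
        "n_dims": clf.n_dims,
        "classes": [
            {
                "label": g.label,
                "components": [
                    {"mean": c.mean.tolist(), "var": c.var.tolist(), "weight": c.weight}
                    for c in g.components
                ],
            }
            for g in clf.classes
        ],
    }


def classifier_from_dict(d: dict) -> GMMClassifier:
    classes = [
        ClassGMM(
            components=[
                GaussianComponent(
                    mean=np.asarray(c["mean"]), var=np.asarray(c["var"]), weight=c["weight"]
                )
                for c in g["components"]
            ],
            label=g.get("label"),
        )
        for g in d["classes"]
    ]
    return GMMClassifier(classes=classes, n_dims=d["n_dims"])


def save_classifier(clf: GMMClassifier, path: str | Path) -> None:
    """Write the classifier to JSON, lossless at double precision."""
    Path(path).write_text(json.dumps(classifier_to_dict(clf), indent=2))


def load_classifier(path: str | Path) -> GMMClassifier:
    return classifier_from_dict(json.loads(Path(path).read_text()))
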