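"""Gaussian-kernel soft-margin SVM with per-training-set z-scoring.

The classifier is a standard two-class soft-margin SVM with the Gaussian
(RBF) kernel

    K(x1, x2) = exp(-||x1 - x2||^2 / (2 sigma^2))

applied to z-scored VOC concentrations, with cancer as the positive class.
The working hyperparameters are sigma = 1.5 and C = 1000, chosen to keep
the support-vector count — the number of training points that actually
pin the boundary — small; a small SV fraction is the parsimony/overfitting
indicator used throughout the subset search.

The dual problem is solved by scikit-learn's libsvm backend; this module
wraps it behind a :class:`SVMModel` that exposes support vectors, signed
dual coefficients, bias and the signed decision function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .cohort import CANCER, VOCTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KernelParams:
    """Gaussian-kernel SVM hyperparameters.

    sigma
        Kernel width on the z-scored feature scale (dimensionless);
        default 1.5.
    c_penalty
        Soft-margin misclassification penalty C > 0; default 1000.
    tol
        Dual-gap stopping tolerance of the solver.
    max_iter
        Hard iteration cap (-1 = unlimited); hitting it logs a warning
        via the solver.
    """

    sigma: float = 1.5
    c_penalty: float = 1000.0
    tol: float = 1e-3
    max_iter: int = 10_000_000

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.c_penalty <= 0:
            raise ValueError("c_penalty must be > 0")

    @property
    def gamma(self) -> float:
        """scikit-learn's RBF coefficient: gamma = 1 / (2 sigma^2)."""
        return 1.0 / (2.0 * self.sigma**2)


@dataclass(frozen=True)
class Scaler:
    """Per-feature z-scoring transform (center = mean, scale = sample SD)."""

    center: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.center) / self.scale


def fit_scaler(train, subset=None) -> Scaler:
    """Fit a z-score scaler on training data.

    ``train`` is a :class:`VOCTable` (with ``subset`` naming the feature
    columns) or a raw 2-D array. Centers are feature means; scales are
    sample standard deviations (ddof=1). A zero-variance feature gets
    scale 1 (and a logged warning), which makes a constant column inert
    after centering rather than dividing by zero.
    """
    if isinstance(train, VOCTable):
        if subset is not None and len(subset) == 0:
            raise ValueError("empty VOC subset")
        X = train.values(subset)
    else:
        X = np.asarray(train, float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("empty feature set")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 training samples to fit a scaler")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero = scale == 0
    if zero.any():
        logger.warning("zero-variance feature(s) at columns %s; scale set to 1",
                       np.flatnonzero(zero).tolist())
        scale = np.where(zero, 1.0, scale)
    return Scaler(center=center, scale=scale)


def gaussian_kernel(x1, x2, params: KernelParams) -> float:
    """K(x1, x2) = exp(-||x1-x2||^2 / (2 sigma^2)) for scaled vectors."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.shape != x2.shape:
        raise ValueError(f"dimension mismatch: {x1.shape} vs {x2.shape}")
    return float(np.exp(-np.sum((x1 - x2) ** 2) / (2.0 * params.sigma**2)))


def kernel_matrix(X, Y, params: KernelParams) -> np.ndarray:
    """Gaussian kernel Gram matrix between rows of X and rows of Y."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * params.sigma**2))


def labels_to_y(labels) -> np.ndarray:
    """Encode class labels as +1 (cancer) / -1 (healthy)."""
    return np.where(np.asarray(labels, object) == CANCER, 1, -1)


@dataclass
class SVMModel:
    """A trained Gaussian-kernel SVM over a VOC subset.

    Decision function: f(x) = sum_i alpha_i y_i K(x_i, x) + b over the
    support vectors, with f > 0 predicting cancer. Satisfies the KKT
    conditions |alpha_i y_i| <= C and sum_i alpha_i y_i = 0.
    """

    subset: tuple
    params: KernelParams
    scaler: Scaler
    _svc: SVC

    @property
    def support_vectors(self) -> np.ndarray:
        """Support vectors in the z-scored feature space."""
        return self._svc.support_vectors_

    @property
    def dual_coefficients(self) -> np.ndarray:
        """Signed dual weights alpha_i y_i, one per support vector."""
        return self._svc.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self._svc.intercept_[0])

    @property
    def n_support(self) -> int:
        return int(self._svc.n_support_.sum())

    def decision_values(self, samples, subset_applied: bool = False) -> np.ndarray:
        """Signed decision value f(x) per sample; positive side = cancer.

        ``samples`` may be a :class:`VOCTable` (the model's VOC subset is
        extracted), or a raw array already restricted to the subset
        features (set ``subset_applied=True`` for raw ppb arrays).
        """
        if isinstance(samples, VOCTable):
            X = samples.values(self.subset)
        else:
            X = np.atleast_2d(np.asarray(samples, float))
            if not subset_applied and X.shape[1] != len(self.subset):
                raise ValueError(
                    f"expected {len(self.subset)} feature columns, got {X.shape[1]}"
                )
        return self._svc.decision_function(self.scaler.transform(X))

    def predict(self, samples, **kw) -> np.ndarray:
        """Predicted labels ('cancer'/'healthy') by decision-value sign."""
        f = self.decision_values(samples, **kw)
        return np.where(f > 0, "cancer", "healthy").astype(object)


def train_svm(train, subset=None, params: KernelParams | None = None,
              scaler: Scaler | None = None, y=None) -> SVMModel:
    """Train the soft-margin Gaussian-kernel SVM on a training cohort.

    ``train`` is a :class:`VOCTable` (with ``subset`` selecting VOC
    columns) or a raw samples x features array with explicit ``y`` labels
    (+1/-1 or 'cancer'/'healthy'). Features are z-scored with a scaler fit
    on this training set unless a pre-fit ``scaler`` is supplied (global
    normalization mode for exact-replication experiments).
    """
    params = params or KernelParams()
    if isinstance(train, VOCTable):
        subset = tuple(subset if subset is not None else train.voc_names)
        X = train.values(subset)
        y_enc = labels_to_y(train.labels)
    else:
        X = np.asarray(train, float)
        if y is None:
            raise ValueError("y labels required for array input")
        y_arr = np.asarray(y)
        y_enc = labels_to_y(y_arr) if y_arr.dtype.kind in "OU" else y_arr.astype(int)
        subset = tuple(subset) if subset is not None else tuple(range(X.shape[1]))
    if len(np.unique(y_enc)) < 2:
        raise ValueError("training data contain a single class")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values in training data")
    if scaler is None:
        scaler = fit_scaler(X)
    svc = SVC(
        C=params.c_penalty,
        kernel="rbf",
        gamma=params.gamma,
        tol=params.tol,
        max_iter=params.max_iter,
        shrinking=True,
        cache_size=64,
    )
    svc.fit(scaler.transform(X), y_enc)
    return SVMModel(subset=subset, params=params, scaler=scaler, _svc=svc)
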