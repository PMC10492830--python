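"""Kernel ridge / minimum-norm regression and minimum-norm linear regression.

A fitted kernel machine is ``f(x) = alpha @ K(X_train, x)`` where the
coefficients solve ``(K_n + lambda I) alpha^T = Y`` (ridge ``lambda > 0``) or
``alpha^T = K_n^+ Y`` (``lambda = 0``, the minimum-norm interpolant).

Conventions
-----------
User-facing sample matrices are rows-as-samples (``n x d``) and label
matrices rows-as-samples (``n x c``).  Predictions are returned with rows as
outputs (``c x m``), matching the coefficient layout ``alpha`` (``c x n``).
The linear theory in :mod:`kerneltransfer.theory` works columns-as-samples
(``X`` is ``d x n``); :func:`min_norm_linear` uses that orientation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.linalg

from .kernels import KernelSpec, gram_matrix

__all__ = ["KernelModel", "LinearModel", "fit_kernel", "predict", "min_norm_linear", "pinv"]


def pinv(A: np.ndarray) -> np.ndarray:
    """Moore-Penrose pseudoinverse with the cutoff ``max(m, n) * eps * sigma_max``.

    Singular values below that threshold are treated as zero, so the rank
    decision is reproducible across problems of different scale.
    """
    A = np.asarray(A, dtype=float)
    return np.linalg.pinv(A, rcond=max(A.shape) * np.finfo(float).eps)


@dataclasses.dataclass
class KernelModel:
    """A fitted kernel regressor.

    Attributes
    ----------
    spec:
        Kernel description.
    X_train:
        Training inputs, ``n x d`` (rows are samples).
    alpha:
        Coefficient matrix, ``c x n``.
    ridge:
        Ridge coefficient ``lambda >= 0`` used in the fit.
    """

    spec: KernelSpec
    X_train: np.ndarray
    alpha: np.ndarray
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.X_train = np.asarray(self.X_train, dtype=float)
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        if self.alpha.shape[1] != self.X_train.shape[0]:
            raise ValueError(
                f"alpha has {self.alpha.shape[1]} columns but X_train has "
                f"{self.X_train.shape[0]} rows"
            )
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    @property
    def n_outputs(self) -> int:
        return self.alpha.shape[0]

    def predict(self, X_new) -> np.ndarray:
        return predict(self, X_new)


@dataclasses.dataclass
class LinearModel:
    """A linear predictor ``x -> W x`` with weight matrix ``W`` (``c x d``)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights contain non-finite entries")

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[0]

    def predict(self, X_new) -> np.ndarray:
        """Predict for rows-as-samples input; returns ``c x m``."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.weights.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: model expects {self.weights.shape[1]}, "
                f"got {X_new.shape[1]}"
            )
        return self.weights @ X_new.T


def _as_labels(Y, n: int) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.ndim != 2 or Y.shape[0] != n:
        raise ValueError(f"label matrix must have {n} rows (one per sample), got shape {Y.shape}")
    return Y


def fit_kernel(spec: KernelSpec, X, Y, ridge: float = 0.0) -> KernelModel:
    """Fit a kernel regressor on ``(X, Y)``.

    With ``ridge > 0`` the coefficients solve ``(K_n + ridge I) alpha^T = Y``;
    with ``ridge = 0`` the minimum-norm solution ``alpha^T = K_n^+ Y`` is
    returned, which interpolates the training labels whenever ``K_n`` is
    nonsingular.  The ridge enters as an unscaled addition to the Gram
    diagonal (not divided by ``n``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least one training sample")
    Y = _as_labels(Y, n)
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    K = gram_matrix(spec, X)
    if ridge > 0:
        A = K + ridge * np.eye(n)
        try:
            c, low = scipy.linalg.cho_factor(A)
            alphaT = scipy.linalg.cho_solve((c, low), Y)
        except scipy.linalg.LinAlgError:
            warnings.warn(
                "regularized Gram matrix is numerically singular; "
                "falling back to the pseudoinverse",
                RuntimeWarning,
            )
            alphaT = pinv(A) @ Y
    else:
        alphaT = pinv(K) @ Y
    return KernelModel(spec=spec, X_train=X, alpha=alphaT.T, ridge=float(ridge))


def predict(model: KernelModel, X_new) -> np.ndarray:
    """Evaluate ``alpha @ K(X_train, X_new)``; returns ``c x m``."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[0] == 0:
        return np.zeros((model.n_outputs, 0))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.X_train.shape[1]}, "
            f"got {X_new.shape[1]}"
        )
    return model.alpha @ gram_matrix(model.spec, model.X_train, X_new)


def min_norm_linear(X, Y) -> LinearModel:
    """Minimum-norm linear least squares, columns-as-samples.

    ``X`` is ``d x n`` (columns are samples) and ``Y`` is ``c x n``.  Returns
    the weight matrix ``W = Y X^+``: among all minimizers of
    ``||Y - W X||_F`` it has minimal Frobenius norm.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"X has {X.shape[1]} samples (columns) but Y has {Y.shape[1]}"
        )
    return LinearModel(weights=Y @ pinv(X))
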