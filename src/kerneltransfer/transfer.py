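"""Transfer operators: projection, translation, and their combination.

Given a frozen source predictor ``f_s`` and a target dataset ``(X_t, Y_t)``:

* **projection** fits a secondary model (the head) on the source model's
  outputs, ``f_p = argmin_f ||Y_t - f(f_s(X_t))||``, and predicts
  ``f_p(f_s(x))``;
* **translation** fits the head on the residuals ``Y_t - f_s(X_t)`` as a
  function of the raw features and predicts ``f_s(x) + f_c(x)``;
* the **combined** operator fits the head on the concatenation
  ``[f_s(x) | x]`` and predicts ``f([f_s(x) | x])``.

Whenever the head fit has infinitely many minimizers (ridge 0 and an
under-determined system) the minimum-norm solution is taken.  Omitting the
feature block of the combined operator recovers projection, and restricting
its head to an additive form recovers translation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Union

import numpy as np

from .kernels import KernelSpec
from .regression import KernelModel, LinearModel, fit_kernel, min_norm_linear, pinv

__all__ = [
    "TransferModel",
    "fit_projected",
    "fit_translated",
    "fit_projected_translated",
    "evaluate_classification",
]

HeadSpec = Union[KernelSpec, str]
SourceModel = Union[KernelModel, LinearModel]

_MODES = ("projected", "translated", "projected_translated")


@dataclasses.dataclass
class TransferModel:
    """A source model composed with a fitted transfer head."""

    mode: str
    source: SourceModel
    head: SourceModel

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown transfer mode {self.mode!r}; expected one of {_MODES}")

    def predict(self, X_new) -> np.ndarray:
        """Predict targets for rows-as-samples input; returns ``c_t x m``."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if self.mode == "projected":
            P = self.source.predict(X_new).T
            return self.head.predict(P)
        if self.mode == "translated":
            return self.source.predict(X_new) + self.head.predict(X_new)
        P = self.source.predict(X_new).T
        return self.head.predict(np.hstack([P, X_new]))


def _fit_head(inputs: np.ndarray, Y: np.ndarray, head_spec: HeadSpec, ridge: float) -> SourceModel:
    """Fit the secondary model on rows-as-samples ``inputs`` against ``Y``."""
    if isinstance(head_spec, KernelSpec):
        return fit_kernel(head_spec, inputs, Y, ridge=ridge)
    if head_spec != "linear":
        raise ValueError(f"head_spec must be a KernelSpec or 'linear', got {head_spec!r}")
    Xc = inputs.T  # p x n, columns-as-samples
    Yc = np.atleast_2d(Y).T if np.asarray(Y).ndim == 1 else np.asarray(Y, dtype=float).T
    if ridge > 0:
        p = Xc.shape[0]
        W = Yc @ Xc.T @ np.linalg.inv(Xc @ Xc.T + ridge * np.eye(p))
        return LinearModel(weights=W)
    return min_norm_linear(Xc, Yc)


def _source_outputs(source: SourceModel, X_t: np.ndarray) -> np.ndarray:
    P = source.predict(X_t).T  # n x c_s
    if P.shape[0] > 1 and float(np.ptp(P, axis=0).max(initial=0.0)) <= 1e-12:
        warnings.warn(
            "source predictions are constant across the target samples; "
            "a projection head can only fit a constant",
            RuntimeWarning,
        )
    return P


def _check_target(X_t, Y_t):
    X_t = np.atleast_2d(np.asarray(X_t, dtype=float))
    Y_t = np.asarray(Y_t, dtype=float)
    if Y_t.ndim == 1:
        Y_t = Y_t[:, None]
    if X_t.shape[0] != Y_t.shape[0]:
        raise ValueError(f"X_t has {X_t.shape[0]} rows but Y_t has {Y_t.shape[0]}")
    return X_t, Y_t


def fit_projected(
    source: SourceModel, X_t, Y_t, head_spec: HeadSpec = "linear", ridge: float = 0.0
) -> TransferModel:
    """Fit the projected predictor: head on source outputs vs. target labels."""
    X_t, Y_t = _check_target(X_t, Y_t)
    P = _source_outputs(source, X_t)
    head = _fit_head(P, Y_t, head_spec, ridge)
    return TransferModel(mode="projected", source=source, head=head)


def fit_translated(
    source: SourceModel, X_t, Y_t, head_spec: HeadSpec = "linear", ridge: float = 0.0
) -> TransferModel:
    """Fit the translated predictor: head on features vs. residual labels.

    Requires the source output dimension to equal the target label dimension;
    use projection or the combined operator when the label sets differ.
    """
    X_t, Y_t = _check_target(X_t, Y_t)
    S = source.predict(X_t).T  # n x c_s
    if S.shape[1] != Y_t.shape[1]:
        raise ValueError(
            f"translation needs matching label dimensions (source outputs "
            f"{S.shape[1]}, target labels {Y_t.shape[1]}); use projected or "
            f"projected_translated mode instead"
        )
    head = _fit_head(X_t, Y_t - S, head_spec, ridge)
    return TransferModel(mode="translated", source=source, head=head)


def fit_projected_translated(
    source: SourceModel, X_t, Y_t, head_spec: HeadSpec = "linear", ridge: float = 0.0
) -> TransferModel:
    """Fit the combined predictor: head on ``[f_s(x) | x]`` vs. target labels.

    The two blocks are concatenated without rescaling; pass pre-standardized
    inputs if the blocks live on different scales.
    """
    X_t, Y_t = _check_target(X_t, Y_t)
    P = _source_outputs(source, X_t)
    head = _fit_head(np.hstack([P, X_t]), Y_t, head_spec, ridge)
    return TransferModel(mode="projected_translated", source=source, head=head)


def evaluate_classification(model, X, Y) -> float:
    """Fraction of samples whose argmax prediction matches the argmax label.

    ``Y`` is one-hot, rows-as-samples.  Ties are broken toward the lowest
    class index (numpy argmax convention).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty sample matrix")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    pred = np.asarray(model.predict(X))  # c x n
    return float(np.mean(np.argmax(pred, axis=0) == np.argmax(Y, axis=1)))
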