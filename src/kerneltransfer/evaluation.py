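"""Screening metrics and logarithmic scaling-law fitting.

The three expression-imputation metrics operate on ``n x d`` prediction and
truth matrices (rows are samples, columns are genes):

* ``pearson_r`` — cosine of the *vectorized* matrices, with no centering;
* ``mean_r2`` — mean over samples of the per-sample coefficient of
  determination, where the null model is the sample's own mean over genes;
* ``mean_cosine_centered`` — mean per-sample cosine similarity after
  subtracting a per-group (e.g. per-cell-line) mean vector, which removes
  the inflation caused by points far from the origin.

Learning curves are summarized by an ordinary least-squares fit of
``score = a * log2(n) + b``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "ScalingFit",
    "pearson_r",
    "mean_r2",
    "mean_cosine_centered",
    "fit_log_law",
    "extrapolate_log_law",
]


class MetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


def _paired(pred, truth):
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return pred, truth


def pearson_r(pred, truth) -> float:
    """Uncentered correlation of the flattened matrices, in [-1, 1]."""
    pred, truth = _paired(pred, truth)
    pv, tv = pred.ravel(), truth.ravel()
    np_, nt = np.linalg.norm(pv), np.linalg.norm(tv)
    if np_ == 0 or nt == 0:
        raise MetricError("pearson_r is undefined for zero-norm inputs")
    return float(np.dot(pv, tv) / (np_ * nt))


def mean_r2(pred, truth) -> float:
    """Mean per-sample R^2 against each sample's own mean over outputs.

    Samples whose truth row is constant have an undefined R^2 and are
    excluded with a warning.
    """
    pred, truth = _paired(pred, truth)
    ybar = truth.mean(axis=1, keepdims=True)
    ss_tot = np.sum((truth - ybar) ** 2, axis=1)
    ok = ss_tot > 0
    if not np.all(ok):
        warnings.warn(
            f"excluding {int(np.sum(~ok))} sample(s) with constant truth rows from mean_r2",
            RuntimeWarning,
        )
    if not np.any(ok):
        raise MetricError("mean_r2 is undefined: every truth row is constant")
    ss_res = np.sum((pred - truth) ** 2, axis=1)
    return float(np.mean(1.0 - ss_res[ok] / ss_tot[ok]))


def mean_cosine_centered(pred, truth, group_of_sample=None, center: str = "truth") -> float:
    """Mean per-sample cosine similarity after per-group mean centering.

    The mean vector of each group is computed from the truth matrix (default)
    or from each matrix separately (``center="each"``) and subtracted from
    every sample of the group before the cosine.  Samples whose centered
    vector has zero norm are excluded with a warning.
    """
    pred, truth = _paired(pred, truth)
    n = pred.shape[0]
    if group_of_sample is None:
        groups = np.zeros(n, dtype=int)
    else:
        groups = np.asarray(group_of_sample)
        if groups.shape != (n,):
            raise ValueError(f"group labels must have shape ({n},), got {groups.shape}")
    if center not in ("truth", "each"):
        raise ValueError("center must be 'truth' or 'each'")
    pred_c = np.empty_like(pred)
    truth_c = np.empty_like(truth)
    for g in np.unique(groups):
        sel = groups == g
        tmean = truth[sel].mean(axis=0)
        pmean = pred[sel].mean(axis=0) if center == "each" else tmean
        truth_c[sel] = truth[sel] - tmean
        pred_c[sel] = pred[sel] - pmean
    pn = np.linalg.norm(pred_c, axis=1)
    tn = np.linalg.norm(truth_c, axis=1)
    ok = (pn > 0) & (tn > 0)
    if not np.all(ok):
        warnings.warn(
            f"excluding {int(np.sum(~ok))} sample(s) with zero-norm centered "
            f"vectors from mean_cosine_centered",
            RuntimeWarning,
        )
    if not np.any(ok):
        raise MetricError("mean_cosine_centered is undefined: all centered vectors are zero")
    cos = np.einsum("ij,ij->i", pred_c[ok], truth_c[ok]) / (pn[ok] * tn[ok])
    return float(np.mean(cos))


@dataclasses.dataclass(frozen=True)
class ScalingFit:
    """Fitted logarithmic learning curve ``score = a * log2(n) + b``."""

    a: float
    b: float
    r_squared: float


def fit_log_law(n_values, scores) -> ScalingFit:
    """Least-squares fit of scores on ``log2(n)``.

    Requires at least two distinct sample counts.  When the scores have zero
    variance the fit is exact (slope 0) and ``r_squared`` is defined as 1.
    """
    n_values = np.asarray(n_values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if n_values.shape != scores.shape or n_values.ndim != 1:
        raise ValueError("n_values and scores must be equal-length 1-D arrays")
    if np.any(n_values <= 0):
        raise ValueError("sample counts must be positive")
    if np.unique(n_values).size < 2:
        raise ValueError("need at least 2 distinct sample counts to fit a scaling law")
    x = np.log2(n_values)
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, scores, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = scores - (a * x + b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((scores - scores.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ScalingFit(a=a, b=b, r_squared=r2)


def extrapolate_log_law(fit: ScalingFit, n) -> float:
    """Evaluate the fitted law ``a * log2(n) + b`` at sample count ``n``."""
    n = float(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    return fit.a * np.log2(n) + fit.b
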