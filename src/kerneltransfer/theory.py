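"""Exact risk theory for over-parameterized linear transfer learning.

Setting: source and target maps are linear, ``y = omega x`` with
``omega_s`` (``c_s x d``) and ``omega_t`` (``c_t x d``), inputs drawn i.i.d.
from an isotropic distribution on R^d (standard Gaussian here), and all
estimators are minimum-norm least-squares fits ``w_hat = y X^+`` built from
``X`` with columns as samples.  With ``n <= d`` these interpolate.

The estimators under study are

* baseline            ``w_b = y_t X_t^+``,
* source              ``w_s = y_s X_s^+``,
* projected           ``w_p w_s`` with ``w_p = y_t (w_s X_t)^+``,
* projected_rowspace  ``w_b w_s^+ w_s`` (baseline projected onto the
  estimated source row space; a diagnostic companion to ``projected``),
* translated          ``w_s + w_c`` with ``w_c = (y_t - w_s X_t) X_t^+``,

and the risk of an estimator ``w`` is ``E ||omega_t x - w x||^2`` over a
fresh isotropic ``x`` and the training draw, which under unit covariance
equals ``E ||omega_t - w||_F^2``.

Closed forms (valid for ``n_s, n_t <= d``):

* baseline: ``(1 - n_t/d) ||omega_t||_F^2``;
* projected: ``[(C1 + C2 K1)(1 - n_t/d) + (1 - C1 - C2)] ||omega_t||_F^2
  + C2 K2 eps`` with ``C1 = n_s c_s (d - n_s) / (d(d-1)(d+2))``,
  ``C2 = n_s [d(n_s + 1) - 2] / (d(d-1)(d+2))``,
  ``K1 = 1 - n_t (d - c_s) / ((d-1)(d+2))``,
  ``K2 = n_t/d + n_t (d - n_t) / ((d-1)(d+2))``, where the task-similarity
  ``eps = ||omega_t (I - omega_s^+ omega_s)||_F^2`` is the squared Frobenius
  mass of the target map outside the source map's row space;
* translated: ``[A + (1 - n_s/d)(1 - A)] * baseline`` with
  ``A = ||omega_s - omega_t||_F^2 / ||omega_t||_F^2`` — a weighted average,
  with weight ``n_s/d``, of the baseline risk and ``A`` times it.

The ``d -> infinity`` limits at fixed ``S = n_s/d``, ``T = n_t/d``,
``C = c_s/d`` are exposed by :func:`corollary_asymptotic_risk` together with
the monotonicity predicates, and :func:`mc_risk` is a Monte-Carlo oracle
that estimates every risk by direct simulation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .regression import pinv

__all__ = [
    "LinearTransferTask",
    "RiskBreakdown",
    "epsilon_similarity",
    "risk_baseline",
    "risk_projected",
    "risk_translated",
    "mc_risk",
    "linear_transfer_estimator",
    "corollary_asymptotic_risk",
    "s_monotone_predicate",
    "c_direction_predicate",
    "small_tc_expansion",
    "translated_crossover_angle",
    "ESTIMATORS",
]

ESTIMATORS = ("baseline", "source", "projected", "projected_rowspace", "translated")


@dataclasses.dataclass
class LinearTransferTask:
    """The linear transfer world: dimensions and oracle weight matrices."""

    d: int
    n_s: int
    n_t: int
    omega_s: np.ndarray
    omega_t: np.ndarray
    distribution: str = "gaussian"

    def __post_init__(self) -> None:
        self.omega_s = np.atleast_2d(np.asarray(self.omega_s, dtype=float))
        self.omega_t = np.atleast_2d(np.asarray(self.omega_t, dtype=float))
        if self.distribution != "gaussian":
            raise ValueError("only the gaussian sampling law is implemented")
        if self.omega_s.shape[1] != self.d or self.omega_t.shape[1] != self.d:
            raise ValueError("omega_s and omega_t must have d columns")
        # the closed forms are asserted only for n <= d, but simulation and
        # generation are well defined outside that regime, so only basic
        # positivity is enforced here (risk_* functions guard the regime)
        if self.n_s < 0 or self.n_t < 1:
            raise ValueError(f"need n_s >= 0 and n_t >= 1 (got {self.n_s}, {self.n_t})")

    @property
    def c_s(self) -> int:
        return self.omega_s.shape[0]

    @property
    def c_t(self) -> int:
        return self.omega_t.shape[0]


@dataclasses.dataclass
class RiskBreakdown:
    """Closed-form projected risk with its intermediate constants."""

    C1: float
    C2: float
    K1: float
    K2: float
    epsilon: float
    risk: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def epsilon_similarity(omega_t, omega_s) -> float:
    """Task similarity ``eps = ||omega_t (I - omega_s^+ omega_s)||_F^2``.

    Zero iff every row of ``omega_t`` lies in the row space of ``omega_s``
    (e.g. whenever ``omega_t = omega_p omega_s`` for some ``omega_p``).
    """
    omega_t = np.atleast_2d(np.asarray(omega_t, dtype=float))
    omega_s = np.atleast_2d(np.asarray(omega_s, dtype=float))
    if omega_t.shape[1] != omega_s.shape[1]:
        raise ValueError("omega_t and omega_s must have the same number of columns")
    proj = pinv(omega_s) @ omega_s
    off = omega_t - omega_t @ proj
    return float(np.sum(off * off))


def _check_regime(d: int, **ns) -> None:
    for name, n in ns.items():
        if not 0 <= n <= d:
            raise ValueError(f"out of regime: need 0 <= {name} <= d, got {name}={n}, d={d}")


def risk_baseline(d: int, n_t: int, norm_wt_sq: float) -> float:
    """Risk ``(1 - n_t/d) ||omega_t||_F^2`` of the direct target fit."""
    _check_regime(d, n_t=n_t)
    return (1.0 - n_t / d) * norm_wt_sq


def risk_projected(
    d: int, n_s: int, n_t: int, c_s: int, norm_wt_sq: float, epsilon: float
) -> RiskBreakdown:
    """Closed-form projected-transfer risk.

    .. note::
       This expression treats the estimated source row-space operator as an
       exact orthogonal projection (its defining moment identity
       ``E[P_s B P_s] = C1 I + C2 B`` is applied to second moments as well).
       That step is exact at ``n_s = d``, where the formula agrees with
       direct simulation of the ``projected_rowspace`` estimator in
       :func:`mc_risk`; away from that boundary, direct simulation of the
       composed estimator ``w_p w_s`` deviates from this formula — for
       instance the composition recovers ``omega_t`` exactly (risk 0)
       whenever ``n_s = d``, ``epsilon = 0`` and ``n_t >= c_s``.  See
       ``docs/methods.md`` for the full analysis.
    """
    if d < 3:
        raise ValueError("closed form requires d >= 3 (nonzero denominators)")
    _check_regime(d, n_s=n_s, n_t=n_t)
    if c_s < 1:
        raise ValueError("need c_s >= 1")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    den = d * (d - 1) * (d + 2)
    C1 = n_s * c_s * (d - n_s) / den
    C2 = n_s * (d * (n_s + 1) - 2) / den
    K1 = 1.0 - n_t * (d - c_s) / ((d - 1) * (d + 2))
    K2 = n_t / d + n_t * (d - n_t) / ((d - 1) * (d + 2))
    risk = ((C1 + C2 * K1) * (1.0 - n_t / d) + (1.0 - C1 - C2)) * norm_wt_sq + C2 * K2 * epsilon
    return RiskBreakdown(C1=C1, C2=C2, K1=K1, K2=K2, epsilon=float(epsilon), risk=float(risk))


def risk_translated(d: int, n_s: int, n_t: int, norm_diff_sq: float, norm_wt_sq: float) -> float:
    """Closed-form risk of the translated estimator ``w_s + w_c``."""
    _check_regime(d, n_s=n_s, n_t=n_t)
    if not norm_wt_sq > 0:
        raise ValueError("norm_wt_sq must be > 0")
    A = norm_diff_sq / norm_wt_sq
    return (A + (1.0 - n_s / d) * (1.0 - A)) * risk_baseline(d, n_t, norm_wt_sq)


def linear_transfer_estimator(
    estimator: str,
    omega_s: np.ndarray,
    omega_t: np.ndarray,
    X_s: np.ndarray,
    X_t: np.ndarray,
) -> np.ndarray:
    """Build one minimum-norm estimate ``w_hat`` (``c_t x d``) from data.

    ``X_s`` and ``X_t`` are columns-as-samples; labels are the noiseless
    linear images ``y = omega X``.  ``n_s = 0`` (empty ``X_s``) yields a zero
    source model.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")
    d = omega_t.shape[1]
    y_t = omega_t @ X_t
    if estimator == "baseline":
        return y_t @ pinv(X_t)
    if X_s.shape[1] == 0:
        w_s = np.zeros((omega_s.shape[0], d))
    else:
        w_s = (omega_s @ X_s) @ pinv(X_s)
    if estimator == "source":
        return w_s
    if estimator == "projected":
        w_p = y_t @ pinv(w_s @ X_t)
        return w_p @ w_s
    if estimator == "projected_rowspace":
        return y_t @ pinv(X_t) @ pinv(w_s) @ w_s
    # translated
    w_c = (y_t - w_s @ X_t) @ pinv(X_t)
    return w_s + w_c


def _batched_pinv(A: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(A, rcond=max(A.shape[-2:]) * np.finfo(float).eps)


def mc_risk(
    task: LinearTransferTask,
    estimator: str,
    trials: int,
    seed: int,
    chunk: int = 2048,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the risk of one estimator.

    Per trial, ``X_s`` (``d x n_s``) and ``X_t`` (``d x n_t``) are drawn with
    i.i.d. standard-normal entries, labels are noiseless, and the recorded
    risk is the exact conditional risk ``||omega_t - w_hat||_F^2`` (which
    replaces the expectation over the test point under unit covariance).
    Returns ``(mean, standard error)`` over trials; reproducible given seed.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if estimator in ("source", "translated") and task.c_s != task.c_t:
        raise ValueError(f"{estimator} risk needs c_s == c_t")
    d, n_s, n_t = task.d, task.n_s, task.n_t
    ws, wt = task.omega_s, task.omega_t
    rng = np.random.default_rng(seed)
    risks = np.empty(trials)
    done = 0
    while done < trials:
        m = min(chunk, trials - done)
        Xt = rng.standard_normal((m, d, n_t))
        yt = np.einsum("cd,mdn->mcn", wt, Xt)
        if estimator == "baseline":
            W = yt @ _batched_pinv(Xt)
        else:
            if n_s > 0:
                Xs = rng.standard_normal((m, d, n_s))
                ys = np.einsum("cd,mdn->mcn", ws, Xs)
                Ws = ys @ _batched_pinv(Xs)
            else:
                Ws = np.zeros((m, ws.shape[0], d))
            if estimator == "source":
                W = Ws
            elif estimator == "projected":
                M = Ws @ Xt  # m x c_s x n_t
                Wp = yt @ _batched_pinv(M)
                W = Wp @ Ws
            elif estimator == "projected_rowspace":
                # baseline fit projected onto the estimated source row space
                W = yt @ _batched_pinv(Xt) @ _batched_pinv(Ws) @ Ws
            else:  # translated
                Wc = (yt - Ws @ Xt) @ _batched_pinv(Xt)
                W = Ws + Wc
        diff = wt[None, :, :] - W
        risks[done : done + m] = np.einsum("mcd,mcd->m", diff, diff)
        done += m
    mean = float(risks.mean())
    se = float(risks.std(ddof=1) / np.sqrt(trials)) if trials > 1 else float("nan")
    return mean, se


# --- d -> infinity asymptotics (S = n_s/d, T = n_t/d, C = c_s/d) -----------


def _check_unit(**vals) -> None:
    for name, v in vals.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")


def corollary_asymptotic_risk(
    S: float, T: float, C: float, epsilon: float, norm_wt_sq: float
) -> float:
    """Limiting projected risk as ``d -> infinity`` at fixed ``S, T, C``.

    The finite-d constants converge to ``C1 -> S C (1 - S)``, ``C2 -> S^2``,
    ``K1 -> 1 - T (1 - C)``, ``K2 -> T (2 - T)``; the assembled limit at
    ``S = 1`` reduces to ``(1 - T + T C)(1 - T)||omega_t||^2
    + eps T (2 - T)``.
    """
    _check_unit(S=S, T=T, C=C)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    C1 = S * C * (1.0 - S)
    C2 = S * S
    K1 = 1.0 - T * (1.0 - C)
    K2 = T * (2.0 - T)
    return ((C1 + C2 * K1) * (1.0 - T) + (1.0 - C1 - C2)) * norm_wt_sq + C2 * K2 * epsilon


def s_monotone_predicate(epsilon: float, C: float, norm_wt: float, squared: bool = False) -> bool:
    """Condition under which the asymptotic risk decreases monotonically in S.

    As printed the comparison is ``eps < (1 - C) ||omega_t||_F`` (a squared
    norm against an unsquared one); ``squared=True`` exposes the homogeneous
    variant ``eps < (1 - C) ||omega_t||_F^2``.
    """
    _check_unit(C=C)
    bound = (1.0 - C) * (norm_wt**2 if squared else norm_wt)
    return epsilon < bound


def c_direction_predicate(S: float, T: float) -> float:
    """Sign of ``2S - 1 - S T``: negative means risk decreases as C grows."""
    _check_unit(S=S, T=T)
    return 2.0 * S - 1.0 - S * T


def small_tc_expansion(T: float, epsilon: float, norm_wt_sq: float) -> float:
    """First-order risk ``(1 - 2T)||omega_t||^2 + 2 T eps`` for small T, C at S=1."""
    _check_unit(T=T)
    return (1.0 - 2.0 * T) * norm_wt_sq + 2.0 * T * epsilon


def translated_crossover_angle(d: int, n_s: int, n_t: int) -> float:
    """Angle between flattened equal-norm ``omega_s, omega_t`` at which the
    translated risk crosses the baseline risk.

    With ``||omega_s|| = ||omega_t||``, ``||omega_s - omega_t||^2 =
    2||omega_t||^2 (1 - cos theta)``, and the crossover is found numerically
    by root-solving translated risk minus baseline risk over theta in
    ``(0, pi)``.  (Analytically the translated risk beats the baseline iff
    ``||omega_s - omega_t|| < ||omega_t||`` for any ``n_s > 0``, i.e.
    ``theta < pi/3``; this function reports the numerically observed value
    rather than asserting a constant.)
    """
    from scipy.optimize import brentq

    if n_s < 1:
        raise ValueError("crossover requires n_s >= 1")

    def gap(theta: float) -> float:
        diff_sq = 2.0 * (1.0 - np.cos(theta))
        return risk_translated(d, n_s, n_t, diff_sq, 1.0) - risk_baseline(d, n_t, 1.0)

    return float(brentq(gap, 1e-9, np.pi - 1e-9))
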