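"""Kernel functions and Gram matrices.

Two kernel families are supported:

* the Laplace kernel ``K(x, z) = exp(-||x - z||_2 / L)`` with bandwidth ``L``
  (in units of input distance), and
* the neural tangent kernel (NTK) of an infinitely wide fully connected ReLU
  network, optionally with a constant offset (bias) feature appended to the
  input.

The NTK is computed by the standard arc-cosine recursion.  Writing
``Sigma^0(x, z) = x.z`` (plus 1 when the offset feature is on) and

.. math::

    \\kappa_0(u) = \\frac{\\pi - \\arccos u}{\\pi}, \\qquad
    \\kappa_1(u) = \\frac{u(\\pi - \\arccos u) + \\sqrt{1 - u^2}}{\\pi},

the covariance and tangent kernels of a network with ``depth`` hidden layers
satisfy

.. math::

    \\Sigma^{l+1}(x, z) = \\sqrt{\\Sigma^l(x,x)\\,\\Sigma^l(z,z)}\\,
        \\kappa_1(\\lambda^l), \\qquad
    \\Theta^{l+1} = \\Theta^l \\kappa_0(\\lambda^l) + \\Sigma^{l+1},

with ``lambda^l`` the correlation ``Sigma^l(x,z) / sqrt(Sigma^l(x,x)
Sigma^l(z,z))`` and ``Theta^0 = Sigma^0``.  The returned kernel value is
``Theta^depth``.  Because ``kappa_1(1) = 1`` the diagonal ``Sigma^l(x, x)``
is constant across layers, which the implementation exploits.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KernelSpec", "kernel_value", "gram_matrix"]

_FAMILIES = ("laplace", "ntk_fc")


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Declarative description of a kernel function.

    Parameters
    ----------
    family:
        ``"laplace"`` or ``"ntk_fc"``.
    bandwidth:
        Laplace bandwidth ``L > 0`` (ignored for the NTK).
    depth:
        Number of hidden layers of the ReLU network (NTK only), ``>= 1``.
    offset:
        If True, a constant bias feature is appended to the input before
        computing the NTK (i.e. ``Sigma^0(x, z) = x.z + 1``).
    """

    family: str
    bandwidth: float = 10.0
    depth: int = 1
    offset: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.family == "laplace" and not self.bandwidth > 0:
            raise ValueError(f"laplace bandwidth must be > 0, got {self.bandwidth}")
        if self.family == "ntk_fc":
            if int(self.depth) != self.depth or self.depth < 1:
                raise ValueError(f"ntk_fc depth must be an integer >= 1, got {self.depth}")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "bandwidth": self.bandwidth,
            "depth": int(self.depth),
            "offset": bool(self.offset),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(
            family=d["family"],
            bandwidth=float(d.get("bandwidth", 10.0)),
            depth=int(d.get("depth", 1)),
            offset=bool(d.get("offset", False)),
        )


def _as_samples(A, name: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[None, :]
    if A.ndim != 2:
        raise ValueError(f"{name} must be a 1-D vector or 2-D sample matrix, got ndim={A.ndim}")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains non-finite entries")
    return A


def _ntk_gram(spec: KernelSpec, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    S = X @ Z.T
    sx = np.einsum("ij,ij->i", X, X)
    sz = np.einsum("ij,ij->i", Z, Z)
    if spec.offset:
        S = S + 1.0
        sx = sx + 1.0
        sz = sz + 1.0
    # kappa_1(1) = 1, so the layerwise diagonal never changes.
    norm = np.sqrt(np.outer(sx, sz))
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(norm > 0, S / np.where(norm > 0, norm, 1.0), 0.0)
    lam = np.clip(lam, -1.0, 1.0)
    theta = S.copy()
    for _ in range(spec.depth):
        ang = np.arccos(lam)
        k0 = (np.pi - ang) / np.pi
        k1 = (lam * (np.pi - ang) + np.sqrt(np.clip(1.0 - lam * lam, 0.0, None))) / np.pi
        sigma = norm * k1
        theta = theta * k0 + sigma
        lam = np.clip(np.where(norm > 0, sigma / np.where(norm > 0, norm, 1.0), 0.0), -1.0, 1.0)
    return theta


def gram_matrix(spec: KernelSpec, X, Z=None) -> np.ndarray:
    """Gram matrix with entry ``(i, j) = K(X[i], Z[j])``.

    ``Z=None`` computes the square training Gram ``K(X, X)``, which is
    symmetrized exactly and is positive semidefinite up to floating-point
    tolerance.
    """
    X = _as_samples(X, "X")
    square = Z is None
    Z = X if square else _as_samples(Z, "Z")
    if X.shape[1] != Z.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: X has {X.shape[1]} columns, Z has {Z.shape[1]}"
        )
    if spec.family == "laplace":
        G = np.exp(-cdist(X, Z, metric="euclidean") / spec.bandwidth)
    else:
        G = _ntk_gram(spec, X, Z)
    if square:
        G = 0.5 * (G + G.T)
    return G


def kernel_value(spec: KernelSpec, x, z) -> float:
    """Evaluate ``K(x, z)`` for two feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: x has {x.size} entries, z has {z.size}")
    if x.size < 1:
        raise ValueError("inputs must have dimension >= 1")
    return float(gram_matrix(spec, x[None, :], z[None, :])[0, 0])
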