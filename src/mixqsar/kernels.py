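"""Kernel functions and Gram-matrix construction.

Four kernel families are supported:

* ``linear``:  K(x, y) = x . y
* ``poly``:    K(x, y) = (gamma x . y + r)^d
* ``trig``:    K(x, y) = sin(pi/2 + sigma ||x - y||^2)
* ``mixed``:   alpha * trig + beta * poly + (1 - alpha - beta) * linear

The mixed kernel is a convex combination balancing the high learning capacity
of the local trigonometric kernel against the generalization of the global
polynomial and linear kernels.  Note the trigonometric kernel has unit
diagonal and is symmetric but is not positive semidefinite in general; the
SVR layer is responsible for handling indefiniteness.

Kernels perform no input scaling; standardize descriptors at the model layer.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import cdist

from mixqsar.errors import ConfigurationError, DataError

FAMILIES = ("linear", "poly", "trig", "mixed")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus all parameters; unused parameters are ignored.

    For ``family="mixed"``, ``weight_trig`` (alpha) and ``weight_poly``
    (beta) must lie in [0, 1] with alpha + beta <= 1; the linear kernel
    receives the remaining weight 1 - alpha - beta.
    """

    family: str = "mixed"
    gamma: float = 1.0
    offset: float = 0.0
    degree: int = 3
    sigma: float = 1.0
    weight_trig: float = 0.5
    weight_poly: float = 0.25

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if int(self.degree) != self.degree or self.degree < 1:
            raise ConfigurationError("degree must be a positive integer")
        if self.family == "mixed":
            a, b = self.weight_trig, self.weight_poly
            if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
                raise ConfigurationError("mixture weights must lie in [0, 1]")
            if a + b > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"weight_trig + weight_poly = {a + b} exceeds 1"
                )
        if self._poly_active and self.gamma <= 0:
            raise ConfigurationError("gamma must be > 0 when the polynomial component is active")
        if self._trig_active and self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0 when the trigonometric component is active")

    @property
    def _poly_active(self) -> bool:
        return self.family == "poly" or (self.family == "mixed" and self.weight_poly > 0)

    @property
    def _trig_active(self) -> bool:
        return self.family == "trig" or (self.family == "mixed" and self.weight_trig > 0)

    @property
    def weight_linear(self) -> float:
        if self.family != "mixed":
            raise ConfigurationError("weight_linear is defined only for the mixed family")
        return 1.0 - self.weight_trig - self.weight_poly

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "KernelSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown kernel fields: {sorted(unknown)}")
        return cls(**mapping)


def _linear_gram(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return X @ Y.T


def _poly_gram(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return (spec.gamma * (X @ Y.T) + spec.offset) ** int(spec.degree)


def _trig_gram(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    sq = cdist(X, Y, metric="sqeuclidean")
    return np.sin(np.pi / 2.0 + spec.sigma * sq)


def gram_matrix(spec: KernelSpec, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Pairwise kernel matrix K[i, j] = k(X_i, Y_j); exactly symmetric if Y is omitted."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    symmetric = Y is None
    Y = X if symmetric else np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise DataError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]} columns")
    if spec.family == "linear":
        G = _linear_gram(X, Y)
    elif spec.family == "poly":
        G = _poly_gram(spec, X, Y)
    elif spec.family == "trig":
        G = _trig_gram(spec, X, Y)
    else:
        a, b = spec.weight_trig, spec.weight_poly
        c = 1.0 - a - b
        G = np.zeros((X.shape[0], Y.shape[0]))
        if a > 0:
            G += a * _trig_gram(spec, X, Y)
        if b > 0:
            G += b * _poly_gram(spec, X, Y)
        if c > 0:
            G += c * _linear_gram(X, Y)
    if symmetric:
        G = 0.5 * (G + G.T)
    return G


def kernel_eval(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    """Evaluate the kernel on a single pair of vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DataError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(gram_matrix(spec, x[None, :], y[None, :])[0, 0])
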