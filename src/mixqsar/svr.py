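"""Epsilon-insensitive support vector regression over a precomputed Gram matrix.

The primal problem minimizes ``1/2 ||w||^2 + C sum(xi + xi*)`` subject to the
epsilon-insensitive tube constraints; it is solved in the kernelized dual, so
the predictor is ``f(x) = sum_j (alpha_j - alpha_j*) K(x_j, x) + b``.  The
dual quadratic program is dispatched to libsvm (scikit-learn's ``SVR`` with a
precomputed kernel); this module owns the Gram-matrix plumbing that makes the
trigonometric and mixed kernels usable:

* the trigonometric and mixed kernels are not positive semidefinite in
  general, so the training Gram matrix is *flip-stabilized* before solving:
  with eigendecomposition K = V diag(w) V^T, the solver sees
  K_flip = V diag(|w|) V^T (a convex QP), and the solver's dual vector
  ``a~`` is transformed back to prediction coefficients
  ``a = V sign(w) V^T a~``.  This makes predictions with the *original*
  kernel exactly consistent on the training set (K a = K_flip a~), which
  neither eigenvalue clipping nor diagonal shifting achieves once the
  negative spectral mass is non-negligible.  The flipped (negative) spectral
  mass is recorded on the model; it is zero for PSD kernels, where the
  transform reduces to the identity.
* descriptors are z-scored by training means/sds in the :class:`KernelSVR`
  estimator, since kernel hyperparameters like sigma are meaningless without
  a fixed input scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR as _LibSVR

from mixqsar.errors import ConfigurationError, ConvergenceError, DataError
from mixqsar.kernels import KernelSpec, gram_matrix


@dataclass(frozen=True)
class SVRConfig:
    cost: float = 1.0
    epsilon: float = 0.1
    solver_tolerance: float = 1e-8
    max_iterations: int = 10_000_000

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ConfigurationError("cost (C) must be > 0")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be >= 0")
        if self.solver_tolerance <= 0:
            raise ConfigurationError("solver_tolerance must be > 0")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass
class SVRModel:
    """Dual-optimal SVR solution over one training Gram matrix.

    ``dual_coef`` are the solver's dual coefficients (they satisfy the box
    constraint |a| <= C and sum to zero); ``prediction_coef`` are the
    flip-transformed coefficients used with the original kernel at predict
    time.  The two coincide whenever the kernel is PSD.
    """

    dual_coef: np.ndarray  # alpha_j - alpha_j^*, full length-n vector
    prediction_coef: np.ndarray
    bias: float
    support_indices: np.ndarray
    config: SVRConfig
    kernel_spec: KernelSpec | None = None
    flipped_mass: float = 0.0  # total negative eigenvalue mass made positive
    training_gram: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_support(self) -> int:
        return len(self.support_indices)


def _flip_stabilize(gram: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Krein-space flip: returns (K_flip, V, sign vector, negative mass).

    Eigenvalues within rounding error of zero keep sign +1 so that PSD
    kernels pass through untouched.
    """
    w, V = np.linalg.eigh(gram)
    tol = 1e-10 * max(1.0, float(np.abs(w).max()))
    signs = np.where(w < -tol, -1.0, 1.0)
    if (signs > 0).all():
        return gram, V, signs, 0.0
    neg_mass = float(-w[w < -tol].sum())
    K = (V * np.abs(w)) @ V.T
    return 0.5 * (K + K.T), V, signs, neg_mass


def fit_svr(
    gram: np.ndarray,
    y: np.ndarray,
    config: SVRConfig,
    kernel_spec: KernelSpec | None = None,
) -> SVRModel:
    """Solve the epsilon-SVR dual on a precomputed training Gram matrix.

    Raises :class:`ConvergenceError` if the solver hits its iteration budget
    instead of silently returning a non-optimal solution.
    """
    gram = np.asarray(gram, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if gram.ndim != 2 or gram.shape[0] != gram.shape[1]:
        raise DataError(f"gram must be square, got shape {gram.shape}")
    if gram.shape[0] != len(y):
        raise DataError(f"gram has {gram.shape[0]} rows but y has {len(y)} entries")
    if not np.allclose(gram, gram.T, atol=1e-8 * max(1.0, np.abs(gram).max())):
        raise DataError("gram matrix is not symmetric")

    K, V, signs, neg_mass = _flip_stabilize(0.5 * (gram + gram.T))
    solver = _LibSVR(
        kernel="precomputed",
        C=config.cost,
        epsilon=config.epsilon,
        tol=config.solver_tolerance,
        max_iter=config.max_iterations,
        cache_size=64,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            solver.fit(K, y)
        except ConvergenceWarning as exc:
            raise ConvergenceError(
                f"SVR dual solver did not converge within {config.max_iterations} iterations"
            ) from exc

    dual = np.zeros(len(y))
    if len(solver.support_):
        dual[solver.support_] = solver.dual_coef_[0]
    if neg_mass > 0.0:
        prediction_coef = (V * signs) @ (V.T @ dual)
    else:
        prediction_coef = dual
    return SVRModel(
        dual_coef=dual,
        prediction_coef=prediction_coef,
        bias=float(solver.intercept_[0]),
        support_indices=np.asarray(solver.support_, dtype=int),
        config=config,
        kernel_spec=kernel_spec,
        flipped_mass=neg_mass,
        training_gram=gram,
    )


def predict_svr(model: SVRModel, gram_query: np.ndarray) -> np.ndarray:
    """Predict from K(train, query): rows index training points, columns queries."""
    gram_query = np.asarray(gram_query, dtype=float)
    if gram_query.ndim == 1:
        gram_query = gram_query[:, None]
    if gram_query.shape[0] != len(model.dual_coef):
        raise DataError(
            f"gram_query has {gram_query.shape[0]} rows, expected {len(model.dual_coef)}"
        )
    return model.prediction_coef @ gram_query + model.bias


def dual_objective(model: SVRModel, gram: np.ndarray, y: np.ndarray) -> float:
    """Value of the (maximized) dual objective at the model's coefficients."""
    a = model.dual_coef
    y = np.asarray(y, dtype=float)
    return float(
        -0.5 * a @ gram @ a - model.config.epsilon * np.abs(a).sum() + y @ a
    )


class KernelSVR:
    """Descriptor-level estimator: standardize, build Gram, fit, predict.

    The sklearn-style fit/predict surface used throughout the pipeline
    (cross-validation fitness, validation statistics, CLI).  Inputs are
    z-scored by training means/sds; constant columns get unit scale.
    """

    def __init__(
        self,
        kernel_spec: KernelSpec | None = None,
        cost: float = 1.0,
        epsilon: float = 0.1,
        solver_tolerance: float = 1e-4,
        max_iterations: int = 200_000,
        standardize: bool = True,
    ) -> None:
        self.kernel_spec = kernel_spec if kernel_spec is not None else KernelSpec()
        self.config = SVRConfig(
            cost=cost,
            epsilon=epsilon,
            solver_tolerance=solver_tolerance,
            max_iterations=max_iterations,
        )
        self.standardize = standardize

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelSVR":
        X = np.asarray(X, dtype=float)
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0.0] = 1.0
            self.scale_ = sd
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Z = (X - self.mean_) / self.scale_
        self.train_inputs_ = Z
        gram = gram_matrix(self.kernel_spec, Z)
        self.model_ = fit_svr(gram, y, self.config, kernel_spec=self.kernel_spec)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ConfigurationError("KernelSVR must be fit before predict")
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        gram_query = gram_matrix(self.kernel_spec, self.train_inputs_, Z)
        return predict_svr(self.model_, gram_query)

    def to_dict(self) -> dict:
        """JSON-compatible snapshot of a fitted model."""
        if not hasattr(self, "model_"):
            raise ConfigurationError("KernelSVR must be fit before serialization")
        return {
            "kernel_spec": self.kernel_spec.to_dict(),
            "cost": self.config.cost,
            "epsilon": self.config.epsilon,
            "solver_tolerance": self.config.solver_tolerance,
            "max_iterations": self.config.max_iterations,
            "standardize": self.standardize,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "train_inputs": self.train_inputs_.tolist(),
            "dual_coef": self.model_.dual_coef.tolist(),
            "prediction_coef": self.model_.prediction_coef.tolist(),
            "bias": self.model_.bias,
            "support_indices": self.model_.support_indices.tolist(),
            "flipped_mass": self.model_.flipped_mass,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "KernelSVR":
        est = cls(
            KernelSpec.from_dict(payload["kernel_spec"]),
            cost=payload["cost"],
            epsilon=payload["epsilon"],
            solver_tolerance=payload["solver_tolerance"],
            max_iterations=payload["max_iterations"],
            standardize=payload["standardize"],
        )
        est.mean_ = np.asarray(payload["mean"], dtype=float)
        est.scale_ = np.asarray(payload["scale"], dtype=float)
        est.train_inputs_ = np.asarray(payload["train_inputs"], dtype=float)
        est.model_ = SVRModel(
            dual_coef=np.asarray(payload["dual_coef"], dtype=float),
            prediction_coef=np.asarray(payload["prediction_coef"], dtype=float),
            bias=float(payload["bias"]),
            support_indices=np.asarray(payload["support_indices"], dtype=int),
            config=est.config,
            kernel_spec=est.kernel_spec,
            flipped_mass=float(payload["flipped_mass"]),
        )
        return est
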