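"""Binary least-squares SVM trained by a single dense linear solve.

The classifier minimizes a ridge-penalized squared-residual objective under
equality constraints, so training reduces to one (N+1)x(N+1) linear
Karush-Kuhn-Tucker system instead of a quadratic program. The kernel is the
Gaussian RBF; prediction is the sign of the kernel expansion plus bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .data import FeatureScaling, standardize_fit
from .exceptions import (
    ConditioningError,
    DegenerateInputError,
    DimensionError,
    DomainError,
    ValidationError,
)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Hyperparameters:
    """Penalty factor ``gamma`` and RBF kernel width ``sigma2``; both > 0."""

    gamma: float
    sigma2: float

    def __post_init__(self):
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise DomainError(f"gamma must be positive, got {self.gamma}")
        if not (np.isfinite(self.sigma2) and self.sigma2 > 0):
            raise DomainError(f"sigma2 must be positive, got {self.sigma2}")


def rbf_kernel(x: np.ndarray, z: np.ndarray, sigma2: float) -> float:
    """Gaussian RBF kernel exp(-||x-z||^2 / (2 sigma2)) for two vectors."""
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape:
        raise DimensionError(f"kernel arguments differ in length: "
                             f"{x.shape[0]} vs {z.shape[0]}")
    if sigma2 <= 0:
        raise DomainError(f"sigma2 must be positive, got {sigma2}")
    d2 = float(np.dot(x - z, x - z))
    return float(np.exp(-d2 / (2.0 * sigma2)))


def rbf_kernel_matrix(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    """RBF Gram matrix between the rows of A and B."""
    if sigma2 <= 0:
        raise DomainError(f"sigma2 must be positive, got {sigma2}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise DimensionError(f"feature dimensions differ: "
                             f"{A.shape[1]} vs {B.shape[1]}")
    return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sigma2))


@dataclass(frozen=True)
class KKTSystem:
    """The (N+1)x(N+1) block system [[0, -Y^T], [Y, Omega + I/gamma]].

    ``rhs`` is [0; 1; ...; 1]; ``omega`` is the label-signed Gram matrix
    Omega_ij = y_i y_j K(x_i, x_j).
    """

    matrix: np.ndarray
    rhs: np.ndarray
    labels: np.ndarray
    omega: np.ndarray


def _validate_training_input(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise DimensionError(f"{X.shape[0]} rows but {y.shape[0]} labels")
    if X.shape[0] < 2:
        raise DegenerateInputError("need at least 2 training points")
    if not np.isfinite(X).all():
        raise ValidationError("training matrix contains non-finite values")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValidationError("labels must be +1/-1")
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("training labels contain a single class")
    return X, y


def build_kkt_system(X: np.ndarray, y: np.ndarray, hyper: Hyperparameters,
                     symmetric: bool = False) -> KKTSystem:
    """Assemble the training system.

    By default the upper-right block is -Y^T; ``symmetric=True`` selects the
    +Y^T variant common in the LS-SVM literature. Both produce the same
    optimality conditions (sum_i alpha_i y_i = 0).
    """
    X, y = _validate_training_input(X, y)
    n = X.shape[0]
    K = rbf_kernel_matrix(X, X, hyper.sigma2)
    omega = np.outer(y, y) * K

    matrix = np.zeros((n + 1, n + 1))
    matrix[0, 1:] = y if symmetric else -y
    matrix[1:, 0] = y
    matrix[1:, 1:] = omega + np.eye(n) / hyper.gamma
    rhs = np.ones(n + 1)
    rhs[0] = 0.0
    return KKTSystem(matrix=matrix, rhs=rhs, labels=y, omega=omega)


@dataclass
class LSSVMModel:
    """A trained binary LS-SVM: training data, multipliers, bias, scaling."""

    train_points: np.ndarray
    train_labels: np.ndarray
    alphas: np.ndarray
    bias: float
    hyper: Hyperparameters
    scaling: FeatureScaling | None = None

    @property
    def n_features(self) -> int:
        return self.train_points.shape[1]

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "train_points": self.train_points.tolist(),
            "train_labels": self.train_labels.tolist(),
            "alphas": self.alphas.tolist(),
            "bias": self.bias,
            "gamma": self.hyper.gamma,
            "sigma2": self.hyper.sigma2,
            "scaling": self.scaling.to_dict() if self.scaling else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LSSVMModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValidationError(
                f"unsupported model format version {d.get('format_version')}")
        scaling = (FeatureScaling.from_dict(d["scaling"])
                   if d.get("scaling") else None)
        return cls(
            train_points=np.asarray(d["train_points"], dtype=float),
            train_labels=np.asarray(d["train_labels"], dtype=float),
            alphas=np.asarray(d["alphas"], dtype=float),
            bias=float(d["bias"]),
            hyper=Hyperparameters(gamma=float(d["gamma"]),
                                  sigma2=float(d["sigma2"])),
            scaling=scaling,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "LSSVMModel":
        return cls.from_dict(json.loads(text))


def fit(X: np.ndarray, y: np.ndarray, hyper: Hyperparameters,
        scale: bool = True, symmetric: bool = False) -> LSSVMModel:
    """Train a binary LS-SVM by solving the KKT system with an LU solve.

    Features are z-score standardized on the training data by default
    (stored in the model and re-applied at query time); ``scale=False``
    disables this. Raises :class:`ConditioningError` when the system is
    singular or the solve residual exceeds 1e-8 relative tolerance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scaling = None
    if scale:
        scaling = standardize_fit(X)
        X = scaling.apply(X)

    system = build_kkt_system(X, y, hyper, symmetric=symmetric)
    try:
        solution = scipy.linalg.solve(system.matrix, system.rhs)
    except scipy.linalg.LinAlgError as exc:
        raise ConditioningError(
            f"KKT system singular for gamma={hyper.gamma}, "
            f"sigma2={hyper.sigma2}") from exc

    residual = system.matrix @ solution - system.rhs
    rel = np.linalg.norm(residual) / max(np.linalg.norm(system.rhs), 1.0)
    if not np.isfinite(solution).all() or rel > 1e-8:
        raise ConditioningError(
            f"KKT solve residual {rel:.2e} too large for "
            f"gamma={hyper.gamma}, sigma2={hyper.sigma2}")

    return LSSVMModel(
        train_points=X,
        train_labels=system.labels,
        alphas=solution[1:],
        bias=float(solution[0]),
        hyper=hyper,
        scaling=scaling,
    )


def decision_values(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """Kernel-expansion decision values sum_i y_i alpha_i K(x, x_i) + b."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise DimensionError(f"query has {X.shape[1]} features, model "
                             f"expects {model.n_features}")
    if model.scaling is not None:
        X = model.scaling.apply(X)
    K = rbf_kernel_matrix(X, model.train_points, model.hyper.sigma2)
    return K @ (model.alphas * model.train_labels) + model.bias


def decision_value(model: LSSVMModel, x: np.ndarray) -> float:
    """Decision value for a single query vector."""
    return float(decision_values(model, np.atleast_2d(x))[0])


def predict(model: LSSVMModel, X: np.ndarray) -> np.ndarray:
    """Predicted +1/-1 labels; a decision value of exactly 0 maps to +1."""
    values = decision_values(model, X)
    return np.where(values >= 0.0, 1.0, -1.0)
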