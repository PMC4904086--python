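"""Two-class RBF-kernel SVM trained by solving its dual problem with SMO.

The classifier solves the box-constrained dual

    min_a  Q(a) = 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j) - sum_i a_i
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C

with the Gaussian kernel

    K(x, x') = exp(-||x - x'||^2 / g^2).

Note the kernel width enters as ``g**2`` in the denominator, not the
``exp(-gamma * ||.||^2)`` parameterization most libraries use; the
conversion is ``gamma = 1 / g**2`` (relevant when comparing against, e.g.,
scikit-learn).

The solver is sequential minimal optimization with maximal-violating-pair
working-set selection (the two-variable subproblem is solved analytically,
the gradient maintained incrementally), stopping when the KKT violation
gap drops below ``tol``.  The bias ``b*`` is the mean of ``y_i - f0(x_i)``
over free support vectors (0 < a_i < C); when none exist it is the
midpoint of the interval the bound support vectors admit.  The decision
function is ``f(x) = sum_i a*_i y_i K(x, x_i) + b*`` and predictions are
its sign, with 0 mapped to +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConvergenceError, ValidationError


@dataclass(frozen=True)
class TrainingSet:
    """Feature rows ``x_i`` with labels ``y_i`` in {-1, +1}."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        x = np.atleast_2d(np.asarray(self.features, dtype=float))
        y = np.asarray(self.labels, dtype=float)
        object.__setattr__(self, "features", x)
        object.__setattr__(self, "labels", y)
        if x.ndim != 2 or not np.all(np.isfinite(x)):
            raise ValidationError("features must be a finite 2-D matrix")
        if y.shape != (x.shape[0],):
            raise ValidationError("labels must match the number of feature rows")
        if x.shape[0] < 2:
            raise ValidationError("at least two samples are required")
        if set(np.unique(y)) != {-1.0, 1.0}:
            raise ValidationError("labels must contain both -1 and +1")


@dataclass(frozen=True)
class SVMModel:
    """Trained model: support vectors, dual coefficients a*_i y_i, bias."""

    support_vectors: np.ndarray
    dual_coefs: np.ndarray
    bias: float
    kernel_width_g: float
    penalty_C: float
    dual_objective: float
    n_iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coefs": self.dual_coefs.tolist(),
            "bias": self.bias,
            "kernel_width_g": self.kernel_width_g,
            "penalty_C": self.penalty_C,
            "dual_objective": self.dual_objective,
            "n_iterations": self.n_iterations,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SVMModel":
        return cls(
            support_vectors=np.asarray(doc["support_vectors"], dtype=float),
            dual_coefs=np.asarray(doc["dual_coefs"], dtype=float),
            bias=float(doc["bias"]),
            kernel_width_g=float(doc["kernel_width_g"]),
            penalty_C=float(doc["penalty_C"]),
            dual_objective=float(doc["dual_objective"]),
            n_iterations=int(doc.get("n_iterations", 0)),
        )


def rbf_kernel(x: np.ndarray, x2: np.ndarray, g: float) -> float:
    """Gaussian similarity exp(-||x - x2||^2 / g^2); symmetric, in (0, 1]."""
    if g <= 0:
        raise ValidationError("kernel width g must be positive")
    d = np.asarray(x, dtype=float) - np.asarray(x2, dtype=float)
    return float(np.exp(-(d @ d) / g**2))


def rbf_kernel_matrix(xa: np.ndarray, xb: np.ndarray, g: float) -> np.ndarray:
    """Pairwise Gaussian kernel matrix between row sets xa and xb."""
    if g <= 0:
        raise ValidationError("kernel width g must be positive")
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    sq = (
        np.sum(xa**2, axis=1)[:, None]
        + np.sum(xb**2, axis=1)[None, :]
        - 2.0 * xa @ xb.T
    )
    return np.exp(-np.maximum(sq, 0.0) / g**2)


def _smo(
    kmat: np.ndarray, y: np.ndarray, c: float, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Maximal-violating-pair SMO on a precomputed kernel matrix.

    Returns (alpha, gradient, final KKT gap, iterations).  The gradient of
    the dual objective, ``grad = Q a - 1`` with ``Q = K * y y^T``, is kept
    incrementally; each iteration costs O(l).
    """
    l = y.size
    q = kmat * np.outer(y, y)
    alpha = np.zeros(l)
    grad = -np.ones(l)
    eps = 1e-12 * max(c, 1.0)
    gap = np.inf
    for it in range(max_iter):
        yg = -y * grad
        up = ((y > 0) & (alpha < c - eps)) | ((y < 0) & (alpha > eps))
        low = ((y > 0) & (alpha > eps)) | ((y < 0) & (alpha < c - eps))
        if not up.any() or not low.any():
            return alpha, grad, 0.0, it
        i = int(np.argmax(np.where(up, yg, -np.inf)))
        j = int(np.argmin(np.where(low, yg, np.inf)))
        gap = yg[i] - yg[j]
        if gap < tol:
            return alpha, grad, float(gap), it
        quad = max(kmat[i, i] + kmat[j, j] - 2.0 * kmat[i, j], 1e-12)
        # step t moves alpha_i by +y_i t and alpha_j by -y_j t
        t = gap / quad
        t_max_i = c - alpha[i] if y[i] > 0 else alpha[i]
        t_max_j = alpha[j] if y[j] > 0 else c - alpha[j]
        t = min(t, t_max_i, t_max_j)
        if t <= 0:
            return alpha, grad, float(gap), it
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        grad += t * (y[i] * q[:, i] - y[j] * q[:, j])
    raise ConvergenceError(
        f"SMO did not reach tolerance {tol:g} within {max_iter} iterations "
        f"(KKT gap {gap:.3e})",
        gap=float(gap),
    )


def train_svm(
    data: TrainingSet,
    C: float,
    g: float,
    tol: float = 1e-6,
    max_iter: int = 200_000,
) -> SVMModel:
    """Solve the dual for (C, g) and assemble the model.

    ``tol`` is the maximal KKT violation allowed at the solution (use a
    tighter value, e.g. 1e-10, when comparing against an exact solver).
    """
    if C <= 0:
        raise ValidationError("penalty C must be positive")
    if g <= 0:
        raise ValidationError("kernel width g must be positive")
    x, y = data.features, data.labels
    kmat = rbf_kernel_matrix(x, x, g)
    alpha, grad, _, n_iter = _smo(kmat, y, C, tol, max_iter)

    objective = float(0.5 * alpha @ grad - 0.5 * alpha.sum())
    # grad_i = y_i f0(x_i) - 1, so yg = y - f0 equals b* on free vectors
    yg = -y * grad
    eps = 1e-8 * max(C, 1.0)
    free = (alpha > eps) & (alpha < C - eps)
    if free.any():
        bias = float(yg[free].mean())
    else:
        up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        low = ((y > 0) & (alpha > eps)) | ((y < 0) & (alpha < C - eps))
        hi = yg[up].max() if up.any() else 0.0
        lo = yg[low].min() if low.any() else 0.0
        bias = float(0.5 * (hi + lo))

    sv = alpha > eps
    return SVMModel(
        support_vectors=x[sv].copy(),
        dual_coefs=(alpha * y)[sv].copy(),
        bias=bias,
        kernel_width_g=float(g),
        penalty_C=float(C),
        dual_objective=objective,
        n_iterations=n_iter,
    )


def decision_values(model: SVMModel, features: np.ndarray) -> np.ndarray:
    """Raw decision values sum_i a*_i y_i K(x, x_i) + b* for feature rows."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if model.support_vectors.size == 0:
        return np.full(x.shape[0], model.bias)
    if x.shape[1] != model.support_vectors.shape[1]:
        raise ValidationError(
            f"feature dimension {x.shape[1]} does not match model "
            f"dimension {model.support_vectors.shape[1]}"
        )
    kmat = rbf_kernel_matrix(x, model.support_vectors, model.kernel_width_g)
    return kmat @ model.dual_coefs + model.bias


def decision_value(model: SVMModel, x: np.ndarray) -> float:
    """Decision value for a single feature vector."""
    return float(decision_values(model, np.atleast_2d(x))[0])


def predict(model: SVMModel, features: np.ndarray) -> np.ndarray:
    """Predicted labels in {-1, +1}; a decision value of 0 maps to +1."""
    vals = decision_values(model, features)
    return np.where(vals >= 0, 1.0, -1.0)


def labels_to_pm1(labels: Sequence[int]) -> np.ndarray:
    """Map trial-level labels {1, 2} to SVM labels {+1, -1}."""
    labels = np.asarray(labels)
    out = np.where(labels == 1, 1.0, -1.0)
    return out


def labels_from_pm1(y: np.ndarray) -> np.ndarray:
    """Map SVM labels {+1, -1} back to trial-level labels {1, 2}."""
    return np.where(np.asarray(y) > 0, 1, 2)
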