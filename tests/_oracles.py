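"""Independent reference computations used by the test suite.

These deliberately avoid the package's own code paths: the SVM oracle
solves the dual as a generic constrained QP (scipy SLSQP), and the CSP
oracle solves the generalized symmetric eigenproblem directly.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from scipy.optimize import minimize


def rbf_matrix(xa, xb, g):
    xa, xb = np.atleast_2d(xa), np.atleast_2d(xb)
    sq = (
        np.sum(xa**2, 1)[:, None]
        + np.sum(xb**2, 1)[None, :]
        - 2 * xa @ xb.T
    )
    return np.exp(-np.maximum(sq, 0) / g**2)


def svm_dual_qp(X, y, C, g):
    """Brute-force solution of the SVM dual via a generic convex solver.

    Returns (alpha, objective, bias, decision_fn).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    l = len(y)
    K = rbf_matrix(X, X, g)
    Q = K * np.outer(y, y)

    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.full(l, min(C, 1.0) / 2),
        jac=lambda a: Q @ a - 1,
        bounds=[(0.0, C)] * l,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 1000},
    )
    alpha = res.x
    obj = float(res.fun)

    f0 = K @ (alpha * y)
    eps = 1e-6 * max(C, 1.0)
    free = (alpha > eps) & (alpha < C - eps)
    if free.any():
        bias = float(np.mean(y[free] - f0[free]))
    else:
        yg = y - f0
        up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        low = ((y > 0) & (alpha > eps)) | ((y < 0) & (alpha < C - eps))
        hi = yg[up].max() if up.any() else 0.0
        lo = yg[low].min() if low.any() else 0.0
        bias = 0.5 * (hi + lo)

    def decision(Xq):
        return rbf_matrix(Xq, X, g) @ (alpha * y) + bias

    return alpha, obj, bias, decision


def generalized_csp_eig(r1, rc):
    """Solve R1 u = lambda Rc u directly; eigenvalues descending."""
    lam, vecs = scipy.linalg.eigh(r1, rc)
    return lam[::-1], vecs[:, ::-1]


def random_spd_pair(rng, n):
    """Two random SPD matrices scaled to unit trace (class covariances)."""
    out = []
    for _ in range(2):
        a = rng.normal(size=(n, n))
        m = a @ a.T + n * 0.05 * np.eye(n)
        out.append(m / np.trace(m))
    return out[0], out[1]


def random_svm_instance(rng, max_l=8):
    """Small random two-class training problem with distinct points."""
    l = int(rng.integers(3, max_l + 1))
    d = int(rng.integers(1, 4))
    X = rng.normal(size=(l, d))
    y = np.ones(l)
    y[: l // 2] = -1
    rng.shuffle(y)
    if len(set(y)) < 2:
        y[0] = -y[0]
    C = float(rng.uniform(0.5, 20))
    g = float(rng.uniform(0.5, 5))
    return X, y, C, g
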