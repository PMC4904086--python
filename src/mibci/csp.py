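"""Common Spatial Patterns (CSP) for two-class trials.

CSP finds linear channel combinations (spatial filters) whose output
variance is maximal for one class and minimal for the other — the textbook
feature extractor for ERD/ERS-based motor-imagery BCIs.  The procedure:

1.  Per trial, the sample covariance is the raw outer product normalized by
    its trace, ``R = E E^T / trace(E E^T)``.  No mean-centering is applied:
    epoched EEG is approximately zero-mean and the trace normalization
    removes per-trial amplitude scale.
2.  Class-mean covariances ``R1_bar`` and ``R2_bar`` are arithmetic means
    over same-class trials; their sum is the composite covariance
    ``Rc = R1_bar + R2_bar``.
3.  ``Rc = B diag(lam) B^T`` yields the whitening matrix
    ``P = diag(lam)^(-1/2) B^T`` with ``P Rc P^T = I``.
4.  The whitened class covariances ``S1 = P R1_bar P^T`` and
    ``S2 = P R2_bar P^T`` share eigenvectors ``U`` and their eigenvalues
    are complementary: ``lambda1 + lambda2 = 1`` elementwise.  A large
    ``lambda1`` entry means the corresponding direction carries most of
    class 1's variance and least of class 2's.
5.  Filters are rows ``u^T P`` for the ``m`` largest- and ``m``
    smallest-``lambda1`` eigenvectors ``u``; projecting a trial gives
    ``Y = W E`` and the classifier consumes log-variance features of Y.

Eigenvalues are sorted descending by ``lambda1`` (ties keep stable index
order) and each filter's sign is fixed so its first nonzero component is
positive, making outputs deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import DegenerateInputError, ValidationError
from .io_epochs import EpochedTrials

#: Tolerance below which an eigenvalue of Rc counts as numerically zero
#: (relative to the largest eigenvalue).
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class ClassCovariances:
    """Mean normalized covariance per class and their sum."""

    r1_bar: np.ndarray
    r2_bar: np.ndarray

    @property
    def rc(self) -> np.ndarray:
        return self.r1_bar + self.r2_bar

    @property
    def n_channels(self) -> int:
        return self.r1_bar.shape[0]


@dataclass(frozen=True)
class SpatialFilterBank:
    """Whitening + projection products of CSP (or of one RCSP class).

    ``projection_w`` holds ``2 * m_pairs`` filters as rows: the ``m`` with
    the largest eigenvalues first, then the ``m`` with the smallest.
    ``eigvals`` is the full descending eigenvalue vector of the whitened
    class-1 (or class-specific) covariance.
    """

    whitener_p: np.ndarray
    eigvecs_u: np.ndarray
    eigvals: np.ndarray
    projection_w: np.ndarray
    m_pairs: int

    def to_dict(self) -> dict:
        return {
            "whitener_p": self.whitener_p.tolist(),
            "eigvecs_u": self.eigvecs_u.tolist(),
            "eigvals": self.eigvals.tolist(),
            "projection_w": self.projection_w.tolist(),
            "m_pairs": self.m_pairs,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SpatialFilterBank":
        return cls(
            whitener_p=np.asarray(doc["whitener_p"], dtype=float),
            eigvecs_u=np.asarray(doc["eigvecs_u"], dtype=float),
            eigvals=np.asarray(doc["eigvals"], dtype=float),
            projection_w=np.asarray(doc["projection_w"], dtype=float),
            m_pairs=int(doc["m_pairs"]),
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-trial feature vectors with their class labels."""

    features: np.ndarray  # (n_trials, n_features)
    labels: np.ndarray  # values in {1, 2}


def trial_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized sample covariance ``E E^T / trace(E E^T)``."""
    e = np.asarray(trial, dtype=float)
    if e.ndim != 2 or e.shape[1] < 2:
        raise ValidationError(f"trial must be N x T with T >= 2; got shape {e.shape}")
    if not np.all(np.isfinite(e)):
        raise ValidationError("trial contains non-finite values")
    outer = e @ e.T
    tr = np.trace(outer)
    if tr <= 0:
        raise DegenerateInputError("trial has zero total power (trace is 0)")
    return outer / tr


def class_mean_covariances(trials: EpochedTrials) -> ClassCovariances:
    """Arithmetic mean of trial covariances per class."""
    present = set(trials.classes.tolist())
    if present != {1, 2}:
        raise ValidationError(
            f"both classes 1 and 2 must be present; found {sorted(present)}"
        )
    means = []
    for label in (1, 2):
        covs = [trial_covariance(t) for t in trials.class_data(label)]
        means.append(np.mean(covs, axis=0))
    return ClassCovariances(r1_bar=means[0], r2_bar=means[1])


def whitening_transform(rc: np.ndarray) -> np.ndarray:
    """Whitening matrix ``P = lam^(-1/2) B^T`` from ``Rc = B lam B^T``.

    ``Rc`` must be symmetric positive definite; a near-zero eigenvalue is an
    error (no silent pseudo-inverse).
    """
    rc = np.asarray(rc, dtype=float)
    if rc.ndim != 2 or rc.shape[0] != rc.shape[1]:
        raise ValidationError(f"Rc must be square; got shape {rc.shape}")
    if not np.allclose(rc, rc.T, atol=1e-10):
        raise ValidationError("Rc must be symmetric")
    lam, b = scipy.linalg.eigh(rc)
    if lam[-1] <= 0 or lam[0] <= _RANK_RTOL * lam[-1]:
        raise DegenerateInputError(
            f"Rc is rank deficient: eigenvalue {lam[0]:.3e} is numerically zero "
            f"(largest is {lam[-1]:.3e})"
        )
    return (b / np.sqrt(lam)).T


def _sign_fix(w: np.ndarray) -> np.ndarray:
    """Make the first nonzero component of each row positive."""
    w = w.copy()
    for row in w:
        nz = np.nonzero(np.abs(row) > 1e-12)[0]
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    return w


def _select_pairs(n: int, m_pairs: int) -> np.ndarray:
    """Indices of the m largest and m smallest eigenvalues (descending order)."""
    return np.concatenate([np.arange(m_pairs), np.arange(n - m_pairs, n)])


def _whitened_eigh(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigendecomposition of a (symmetrized) whitened covariance."""
    s = 0.5 * (s + s.T)
    lam, u = scipy.linalg.eigh(s)
    return lam[::-1], u[:, ::-1]


def csp_filters(cov: ClassCovariances, m_pairs: int = 1) -> SpatialFilterBank:
    """Build the CSP filter bank from class-mean covariances.

    The whitened class-1 covariance ``S1 = P R1_bar P^T`` is
    eigendecomposed as ``U lambda1 U^T`` with eigenvalues sorted
    descending; the returned projection has ``2 * m_pairs`` rows
    ``u^T P`` for the extreme eigenvectors.  ``U`` simultaneously
    diagonalizes ``S2`` since ``S1 + S2 = I``.
    """
    n = cov.n_channels
    if m_pairs < 1 or 2 * m_pairs > n:
        raise ValidationError(
            f"m_pairs must satisfy 1 <= 2*m_pairs <= n_channels; got "
            f"m_pairs={m_pairs}, n_channels={n}"
        )
    p = whitening_transform(cov.rc)
    lam1, u = _whitened_eigh(p @ cov.r1_bar @ p.T)
    sel = _select_pairs(n, m_pairs)
    w = _sign_fix(u[:, sel].T @ p)
    return SpatialFilterBank(
        whitener_p=p, eigvecs_u=u, eigvals=lam1, projection_w=w, m_pairs=m_pairs
    )


def apply_filters(bank: SpatialFilterBank, trial: np.ndarray) -> np.ndarray:
    """Project a trial through the bank: ``Y = W E``."""
    e = np.asarray(trial, dtype=float)
    if e.ndim != 2 or e.shape[0] != bank.projection_w.shape[1]:
        raise ValidationError(
            f"trial has {e.shape[0] if e.ndim == 2 else '?'} channels; "
            f"filters expect {bank.projection_w.shape[1]}"
        )
    return bank.projection_w @ e


def log_variance_features(y: np.ndarray, variant: str = "standard") -> np.ndarray:
    """Log-variance feature vector of a projected trial.

    ``standard``
        ``f_j = log(var(Y_j) / sum_k var(Y_k))`` — scale invariant; the
        conventional CSP feature.
    ``as_printed``
        ``f_j = log(var(Y_j)) / sum_k log(var(Y_k))`` — the literal reading
        of the normalized-log form some texts print; provided for
        comparison, not recommended (not scale invariant).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValidationError("Y must be a 2-D (filters x samples) matrix")
    var = y.var(axis=1)
    if np.any(var <= 0):
        raise DegenerateInputError(
            f"zero-variance filtered row(s) at index {np.nonzero(var <= 0)[0].tolist()}"
        )
    if variant == "standard":
        return np.log(var / var.sum())
    if variant == "as_printed":
        logs = np.log(var)
        denom = logs.sum()
        if denom == 0:
            raise DegenerateInputError("sum of log-variances is zero")
        return logs / denom
    raise ValidationError(f"unknown variant {variant!r}")


def features_for_trials(
    bank: SpatialFilterBank, trials: EpochedTrials, variant: str = "standard"
) -> FeatureMatrix:
    """Log-variance features for every trial in a container."""
    feats = np.stack(
        [log_variance_features(apply_filters(bank, t), variant) for t in trials.data]
    )
    return FeatureMatrix(features=feats, labels=trials.labels.copy())
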