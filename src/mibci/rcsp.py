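"""Regularized CSP: borrowing covariance structure across subjects.

With few trials from the subject of interest (the *main* subject), the
class covariance estimates that CSP diagonalizes are noisy.  RCSP shrinks
them with two parameters, both in [0, 1]:

``beta``
    mixes the main subject's class covariance with the pooled covariance
    of ``n - 1`` *secondary* subjects (cross-subject transfer);
``gamma``
    shrinks the mixed covariance toward a scaled identity
    (Ledoit-Wolf-style ridge), preserving its trace exactly.

For class ``j`` the regularized covariance is::

    S_j = ((1 - beta) * R_j + beta * Rhat_j) / ((1 - beta) * m + beta * (n - 1) * m)
    Z_j = (1 - gamma) * S_j + (gamma / N) * trace(S_j) * I

where ``R_j`` is the SUM of trace-normalized trial covariances over the
main subject's ``m`` class-``j`` trials and ``Rhat_j`` the sum over the
``(n - 1) * m`` secondary-subject trials (each secondary subject must
contribute exactly ``m`` trials per class, which is what makes the shared
denominator a plain trial count).

Filters are then derived per class: whiten ``Z1 + Z2``, eigendecompose
each whitened ``Z_j`` separately, and keep its extreme eigenvectors.  This
yields two banks W1, W2; classification features concatenate the
log-variance features of both projections (4 * m_pairs values per trial).
With ``beta = gamma = 0`` and a single subject the whole construction
collapses to plain CSP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .csp import (
    SpatialFilterBank,
    _select_pairs,
    _sign_fix,
    _whitened_eigh,
    apply_filters,
    log_variance_features,
    trial_covariance,
    whitening_transform,
)
from .errors import ConfigurationError, ValidationError
from .io_epochs import EpochedTrials


@dataclass(frozen=True)
class RCSPConfig:
    """Regularization setting: (beta, gamma) plus the trial bookkeeping."""

    beta: float
    gamma: float
    m_trials_main: int
    n_subjects: int = 1
    m_pairs: int = 1

    def __post_init__(self):
        if not 0 <= self.beta <= 1:
            raise ConfigurationError("beta must lie in [0, 1]")
        if not 0 <= self.gamma <= 1:
            raise ConfigurationError("gamma must lie in [0, 1]")
        if self.m_trials_main < 1:
            raise ConfigurationError("m_trials_main must be positive")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.m_pairs < 1:
            raise ConfigurationError("m_pairs must be positive")
        if self.denominator <= 0:
            raise ConfigurationError(
                "effective trial count (1-beta)*m + beta*(n-1)*m is zero "
                "(beta = 1 with a single subject)"
            )

    @property
    def denominator(self) -> float:
        m, n = self.m_trials_main, self.n_subjects
        return (1 - self.beta) * m + self.beta * (n - 1) * m


@dataclass(frozen=True)
class RegularizedCovariances:
    """Regularized class covariances Z1, Z2 with their provenance."""

    z1: np.ndarray
    z2: np.ndarray
    config: RCSPConfig


def class_covariance_sums(trials: EpochedTrials) -> dict[int, np.ndarray]:
    """Sum (not mean) of trace-normalized trial covariances per class."""
    out = {}
    for label in (1, 2):
        block = trials.class_data(label)
        if block.shape[0] == 0:
            raise ValidationError(f"class {label} has no trials")
        out[label] = np.sum([trial_covariance(t) for t in block], axis=0)
    return out


def regularized_class_covariance(
    r_main: np.ndarray, r_secondary: np.ndarray, cfg: RCSPConfig
) -> np.ndarray:
    """One class's regularized covariance Z_j(gamma, beta).

    ``r_main``/``r_secondary`` are covariance *sums* over m and (n-1)*m
    trials respectively.  The gamma term redistributes variance onto the
    diagonal without changing the trace.
    """
    r_main = np.asarray(r_main, dtype=float)
    r_secondary = np.asarray(r_secondary, dtype=float)
    if r_main.shape != r_secondary.shape or r_main.ndim != 2:
        raise ValidationError("covariance sums must be square matrices of equal shape")
    n_ch = r_main.shape[0]
    s = ((1 - cfg.beta) * r_main + cfg.beta * r_secondary) / cfg.denominator
    return (1 - cfg.gamma) * s + (cfg.gamma / n_ch) * np.trace(s) * np.eye(n_ch)


def regularized_covariances(
    main: EpochedTrials,
    secondary: Sequence[EpochedTrials],
    beta: float,
    gamma: float,
    m_pairs: int = 1,
) -> RegularizedCovariances:
    """Build Z1, Z2 from a main subject and its secondary subjects.

    Every subject (main and secondary) must contribute the same number of
    trials per class; unequal counts are rejected rather than silently
    reweighted.
    """
    main_sums = class_covariance_sums(main)
    m1 = int(np.sum(main.labels == 1))
    m2 = int(np.sum(main.labels == 2))
    if m1 != m2:
        raise ValidationError(
            f"main subject must have equal trials per class; got {m1} vs {m2}"
        )
    sec1 = np.zeros_like(main_sums[1])
    sec2 = np.zeros_like(main_sums[2])
    for k, subj in enumerate(secondary):
        if subj.n_channels != main.n_channels:
            raise ValidationError(
                f"secondary subject {k + 1} has {subj.n_channels} channels; "
                f"main has {main.n_channels}"
            )
        counts = [int(np.sum(subj.labels == lab)) for lab in (1, 2)]
        if counts != [m1, m1]:
            raise ValidationError(
                f"secondary subject {k + 1} must contribute {m1} trials per "
                f"class; got {counts}"
            )
        sums = class_covariance_sums(subj)
        sec1 += sums[1]
        sec2 += sums[2]
    cfg = RCSPConfig(
        beta=beta,
        gamma=gamma,
        m_trials_main=m1,
        n_subjects=1 + len(secondary),
        m_pairs=m_pairs,
    )
    return RegularizedCovariances(
        z1=regularized_class_covariance(main_sums[1], sec1, cfg),
        z2=regularized_class_covariance(main_sums[2], sec2, cfg),
        config=cfg,
    )


def rcsp_filters(
    z: RegularizedCovariances, m_pairs: int | None = None
) -> tuple[SpatialFilterBank, SpatialFilterBank]:
    """Class-specific filter banks (W1, W2) from regularized covariances.

    The composite Z1 + Z2 is whitened by P; each whitened class covariance
    is eigendecomposed on its own (descending eigenvalues) and its extreme
    eigenvectors mapped back through P.  The two whitened covariances sum
    to the identity, so their eigenvalue spectra are complementary.
    """
    if m_pairs is None:
        m_pairs = z.config.m_pairs
    n = z.z1.shape[0]
    if m_pairs < 1 or 2 * m_pairs > n:
        raise ValidationError(
            f"m_pairs must satisfy 1 <= 2*m_pairs <= n_channels; got "
            f"m_pairs={m_pairs}, n_channels={n}"
        )
    p = whitening_transform(z.z1 + z.z2)
    banks = []
    for zj in (z.z1, z.z2):
        lam, u = _whitened_eigh(p @ zj @ p.T)
        sel = _select_pairs(n, m_pairs)
        w = _sign_fix(u[:, sel].T @ p)
        banks.append(
            SpatialFilterBank(
                whitener_p=p,
                eigvecs_u=u,
                eigvals=lam,
                projection_w=w,
                m_pairs=m_pairs,
            )
        )
    return banks[0], banks[1]


def rcsp_features(
    bank1: SpatialFilterBank,
    bank2: SpatialFilterBank,
    trial: np.ndarray,
    variant: str = "standard",
) -> np.ndarray:
    """Concatenated log-variance features from both class banks (length 4m)."""
    f1 = log_variance_features(apply_filters(bank1, trial), variant)
    f2 = log_variance_features(apply_filters(bank2, trial), variant)
    return np.concatenate([f1, f2])
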