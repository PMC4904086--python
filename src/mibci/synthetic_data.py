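"""Synthetic two-class EEG-like trial generator.

Motor-imagery EEG classification with spatial filters rests on one physical
fact: imagining a movement modulates the *variance* (band power) of sources
over sensorimotor cortex (ERD/ERS), so the two classes differ in the spatial
covariance of the recorded channels.  This module emulates exactly that —
and nothing else.

Generative model
----------------
``n_channels`` latent sources emit i.i.d. Gaussian samples.  Class 1 gives
the first ``n_discriminative_sources`` sources variance ``variance_ratio``
(the rest variance 1); class 2 uses the reversed variance pattern, so the
discriminative power sits on opposite sources for the two classes (for two
channels and one discriminative source with ratio ``v``: class-1 source
variances ``(v, 1)``, class-2 ``(1, v)``).  Sources are mixed into channels
by a fixed random *orthogonal* matrix (QR of a seeded Gaussian draw), and
isotropic sensor noise of standard deviation ``noise_std`` is added.

Because the mixing is orthogonal, the population channel covariances are
known exactly::

    Sigma_j = A @ diag(source_variances_j) @ A.T + noise_std**2 * I

which makes every downstream stage (whitening, simultaneous
diagonalization, eigenvalue recovery) checkable against closed forms.

What this deliberately does *not* model: mu/beta band structure, 1/f
background spectra, artifacts, or inter-trial nonstationarity.  Passing
tests on these data validate the covariance-driven machinery, not
robustness to real EEG's temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .io_epochs import EpochedTrials


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the experimental setting the package targets: a
    two-channel (C3/C4-like) montage sampled at 100 Hz, 3.5 s imagery
    epochs (350 samples), 140 trials per class, one discriminative source
    with a moderate 2:1 ERD-style variance contrast and unit-scale sensor
    noise of 0.5.
    """

    n_channels: int = 2
    n_samples_per_trial: int = 350
    n_trials_per_class: int = 140
    variance_ratio: float = 2.0
    n_discriminative_sources: int = 1
    mixing_seed: int = 0
    noise_std: float = 0.5
    sampling_rate_hz: float = 100.0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be a positive integer")
        if self.n_samples_per_trial < 2:
            raise ConfigurationError("n_samples_per_trial must be >= 2")
        if self.n_trials_per_class < 1:
            raise ConfigurationError("n_trials_per_class must be positive")
        if self.variance_ratio < 1:
            raise ConfigurationError("variance_ratio must be >= 1")
        if not 0 <= self.n_discriminative_sources <= self.n_channels:
            raise ConfigurationError(
                "n_discriminative_sources must lie in [0, n_channels]"
            )
        if self.noise_std < 0:
            raise ConfigurationError("noise_std must be nonnegative")
        if not self.sampling_rate_hz > 0:
            raise ConfigurationError("sampling_rate_hz must be positive")


def source_variances(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-source signal variances for class 1 and class 2.

    Class 1 boosts the leading ``n_discriminative_sources`` sources to
    ``variance_ratio``; class 2 uses the reversed pattern.  With
    ``variance_ratio == 1`` the two classes are identical in expectation.
    """
    v1 = np.ones(config.n_channels)
    v1[: config.n_discriminative_sources] = config.variance_ratio
    return v1, v1[::-1].copy()


def mixing_matrix(config: SyntheticConfig) -> np.ndarray:
    """Fixed orthogonal source-to-channel mixing, reproducible from the seed."""
    rng = np.random.default_rng(config.mixing_seed)
    gauss = rng.standard_normal((config.n_channels, config.n_channels))
    q, r = np.linalg.qr(gauss)
    # fix the sign ambiguity of QR so the matrix is unique
    q = q * np.sign(np.diag(r))
    return q


def population_covariances(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact class channel covariances A diag(v_j) A^T + noise_std^2 I."""
    a = mixing_matrix(config)
    v1, v2 = source_variances(config)
    noise = config.noise_std**2 * np.eye(config.n_channels)
    return a @ np.diag(v1) @ a.T + noise, a @ np.diag(v2) @ a.T + noise


def generate_two_class_trials(config: SyntheticConfig) -> EpochedTrials:
    """Draw a balanced two-class trial set; bit-reproducible from the config.

    Trials are ordered class 1 first, then class 2, with labels {1, 2}.
    The mixing matrix depends only on ``mixing_seed``; the signal and noise
    streams are drawn from the same seeded generator, so identical configs
    produce identical arrays.
    """
    a = mixing_matrix(config)
    v1, v2 = source_variances(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.mixing_seed, 1)))
    n, N, T = config.n_trials_per_class, config.n_channels, config.n_samples_per_trial

    def draw(stds: np.ndarray) -> np.ndarray:
        sources = rng.standard_normal((n, N, T)) * stds[:, None]
        x = np.einsum("cd,ndt->nct", a, sources)
        if config.noise_std > 0:
            x = x + config.noise_std * rng.standard_normal((n, N, T))
        return x

    data = np.concatenate([draw(np.sqrt(v1)), draw(np.sqrt(v2))])
    labels = np.concatenate([np.ones(n, dtype=int), np.full(n, 2, dtype=int)])
    names = tuple(f"ch{i + 1:02d}" for i in range(N))
    return EpochedTrials(
        data=data,
        labels=labels,
        channel_names=names,
        sampling_rate_hz=config.sampling_rate_hz,
    )
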