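import numpy as np
import pytest

from mibci import EpochedTrials, SyntheticConfig, generate_two_class_trials


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_trials():
    """Four 3-channel trials, two per class, deterministic content."""
    rng = np.random.default_rng(7)
    data = rng.normal(size=(4, 3, 20))
    return EpochedTrials(
        data=data,
        labels=np.array([1, 1, 2, 2]),
        channel_names=("C3", "Cz", "C4"),
        sampling_rate_hz=100.0,
    )


@pytest.fixture
def separable_trials():
    """Noise-free 2-channel set with a strong 4:1 variance contrast."""
    cfg = SyntheticConfig(
        n_channels=2,
        n_samples_per_trial=500,
        n_trials_per_class=60,
        variance_ratio=4.0,
        n_discriminative_sources=1,
        mixing_seed=11,
        noise_std=0.0,
    )
    return generate_two_class_trials(cfg)


@pytest.fixture
def noisy_trials():
    """Moderately noisy 6-channel set; accuracy well below ceiling."""
    cfg = SyntheticConfig(
        n_channels=6,
        n_samples_per_trial=100,
        n_trials_per_class=40,
        variance_ratio=1.6,
        n_discriminative_sources=2,
        mixing_seed=21,
        noise_std=1.5,
    )
    return generate_two_class_trials(cfg)
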