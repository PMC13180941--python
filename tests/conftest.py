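import numpy as np
import pytest

from bmnabc import MSEParams, SynthConfig, extract_eeg_features, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """24 signal-level trials (3 participants x 8), planted defaults."""
    return generate_dataset(
        SynthConfig(n_participants=3, trials_per_participant=8, seed=3)
    )


@pytest.fixture(scope="session")
def small_eeg_features(small_dataset):
    """MSE features of the small dataset at a reduced scale range."""
    return extract_eeg_features(
        small_dataset, mse=MSEParams(max_tau=5, min_points=150)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
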