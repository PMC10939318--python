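import numpy as np
import pytest

from gaitkit.synthetic_gait import GaitProfile, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """Noise-free 10-stride session at 204.8 Hz, shared across tests."""
    return simulate_session(GaitProfile(n_strides=10))


@pytest.fixture(scope="session")
def noisy_session():
    """Same walk with small seeded sensor noise."""
    return simulate_session(
        GaitProfile(n_strides=10, gyro_noise_sigma=0.1, acc_noise_sigma=0.02,
                    seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
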