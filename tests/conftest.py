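import numpy as np
import pytest

from sprscreen.synthetic import SyntheticSpec, generate_cycle_set

TRUE_KON = 1e5
TRUE_KOFF = 0.5
TRUE_RMAX = 200.0


@pytest.fixture
def noise_free_cycle_set():
    """Ideal 1:1 binding series with no noise, drift or bulk artifacts."""
    return generate_cycle_set(SyntheticSpec(
        k_on=TRUE_KON, k_off=TRUE_KOFF, R_max=TRUE_RMAX, noise_sd=0.0, seed=0))


@pytest.fixture
def noisy_cycle_set():
    """Screen-like series with 0.5 RU Gaussian noise."""
    return generate_cycle_set(SyntheticSpec(
        k_on=TRUE_KON, k_off=TRUE_KOFF, R_max=TRUE_RMAX, noise_sd=0.5, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
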