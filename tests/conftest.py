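import numpy as np
import pytest

from pathodyn.fitting import ModelConfig
from pathodyn.synthetic_data import generate_cohort, generate_connectome


@pytest.fixture(scope="session")
def small_connectome():
    return generate_connectome(16, density=0.3, seed=1)


@pytest.fixture(scope="session")
def fast_config():
    """Short forward-model profile: 80 s retained window (117 TR frames)."""
    from dataclasses import replace
    return replace(ModelConfig(), duration=95.0, burn_in=15.0)


@pytest.fixture(scope="session")
def small_cohort(small_connectome):
    cohort, truth = generate_cohort(small_connectome, n_cu=4, n_ad=4,
                                    theta_scale=0.8, seed=2)
    return cohort, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
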