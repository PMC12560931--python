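import numpy as np
import pytest

from meatq.config import AcquisitionConfig, default_cohort_config, default_sensory_config
from meatq.datatypes import NmrParams


@pytest.fixture
def default_params() -> NmrParams:
    """Typical loin relaxation parameters: small fast pool, dominant
    intra-myofibrillar pool, minor inter-myofibrillar pool."""
    return NmrParams(p_2f=0.05, p_21=0.85, p_22=0.10, t_21_ms=40.0, t_22_ms=150.0)


@pytest.fixture
def noiseless_acq() -> AcquisitionConfig:
    return AcquisitionConfig(noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


@pytest.fixture
def small_cohort_config():
    return default_cohort_config(n_carcasses=20, seed=7)


@pytest.fixture
def small_sensory_config():
    cfg = default_sensory_config()
    cfg.consumers_per_sample = 5
    cfg.samples_per_session = 8
    cfg.participants_per_session = 10
    return cfg
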