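import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prsdelta.config import SimulationConfig
from prsdelta.simulate import simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_individuals=120, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def covariates(small_cohort) -> pd.DataFrame:
    p = small_cohort.phenotypes
    return pd.DataFrame({"age": p["age"], "sex": p["sex"], "bmi": p["BMI_T1"]})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
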