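import numpy as np
import pytest
from hypothesis import settings

from dbc import prepare_cohort
from dbc.simulate import SynthConfig, generate_cohort
from dbc.windowing import WindowConfig

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient synthetic cohort, truncated and filtered."""
    return prepare_cohort(generate_cohort(SynthConfig(n_patients=120, seed=1)))


@pytest.fixture(scope="session")
def window_config():
    """Window setting with the observation window deep in the pre-event decline."""
    return WindowConfig(observation_minutes=60, prediction_minutes=5, test_minutes=60)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
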