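import numpy as np
import pytest

from augbin.cohort import bor_preset, generate_dataset, table1_preset, two_arm_preset
from augbin.data import EndpointSpec
from augbin.mvnfit import fit_model


@pytest.fixture(scope="session")
def t2_dataset():
    """A single-arm fixed-time T=2 cohort (75 patients)."""
    return generate_dataset(table1_preset(2).config, seed=20240101)


@pytest.fixture(scope="session")
def t2_fit(t2_dataset):
    return fit_model(t2_dataset, 2)


@pytest.fixture(scope="session")
def t2_spec():
    return EndpointSpec("fixed_time", T=2)


@pytest.fixture(scope="session")
def bor_dataset():
    """A single-arm BOR T=4 cohort (75 patients)."""
    return generate_dataset(bor_preset(4).config, seed=20240102)


@pytest.fixture(scope="session")
def bor_fit(bor_dataset):
    return fit_model(bor_dataset, 4)


@pytest.fixture(scope="session")
def two_arm_dataset():
    """A two-arm fixed-time T=2 cohort (75 per arm) under the null."""
    return generate_dataset(two_arm_preset("fixed", tau=0.0).config, seed=20240103)


@pytest.fixture(scope="session")
def two_arm_fit(two_arm_dataset):
    return fit_model(two_arm_dataset, 2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987)
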