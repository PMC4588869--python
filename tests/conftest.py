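import numpy as np
import pytest

from methscreen.dmr import GroupDesign
from methscreen.synthetic import SimulationConfig, simulate_array_cohort


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(n_regions=300, n_true_dmrs=8, seed=42)


@pytest.fixture(scope="session")
def array_cohort(default_config):
    return simulate_array_cohort(default_config)


@pytest.fixture(scope="session")
def design(array_cohort):
    return GroupDesign.from_labels(array_cohort.group_labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
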