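import numpy as np
import pytest

from phantomrad.study import StudyConfig, run_suite


@pytest.fixture(scope="session")
def compact_config():
    return StudyConfig.compact()


@pytest.fixture(scope="session")
def compact_table(compact_config):
    """One full compact study run shared across tests."""
    return run_suite(compact_config, seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
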