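import numpy as np
import pytest

from gliongs.preprocess import log_transform_tpm
from gliongs.simulate import SimConfig, generate_expression


@pytest.fixture(scope="session")
def sim_dataset():
    """Default-condition synthetic glioma dataset (TPM protocol)."""
    config = SimConfig(seed=11)
    matrix, truth = generate_expression(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def sim_normalized(sim_dataset):
    _config, matrix, _truth = sim_dataset
    return log_transform_tpm(matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
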