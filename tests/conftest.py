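import numpy as np
import pytest

from chromvalence import synthetic as syn


@pytest.fixture(scope="session")
def default_dataset():
    """Shared small instance of the 8-mark confounded-repressor scenario."""
    return syn.default_scenario(n_genes=1500, seed=11,
                                simulate_profile_data=False)


@pytest.fixture(scope="session")
def default_amplitudes(default_dataset):
    return default_dataset.ground_truth.true_amplitudes.to_numpy()


@pytest.fixture(scope="session")
def default_expression(default_dataset):
    return default_dataset.ground_truth.expression.to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
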