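import warnings

import pytest

import lncpanel as lp

# near-identical replicate rows trip scipy's catastrophic-cancellation
# warning in the t-test; it is expected for planted low-noise probes
warnings.filterwarnings(
    "ignore", message="Precision loss occurred", category=RuntimeWarning
)


@pytest.fixture(scope="session")
def sim_config():
    """Default synthetic study design (3 pairs, 600+600 probes)."""
    return lp.SimConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(sim_config):
    """(matrix, truth) generated once per session."""
    return lp.generate_expression(sim_config)


@pytest.fixture(scope="session")
def annotation(sim_config, dataset):
    _, truth = dataset
    return lp.generate_annotation(sim_config, truth)
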