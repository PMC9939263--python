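import numpy as np
import pytest

from agesocnet import experiments, synth


@pytest.fixture(scope="session")
def default_dataset():
    """One 19-network synthetic dataset at default parameters."""
    params = synth.SynthParams()
    rng = np.random.default_rng(7)
    networks, truth = synth.generate_dataset(params, rng=rng)
    return params, networks, truth


@pytest.fixture(scope="session")
def measured_dataset(default_dataset):
    """Node and global metric tables for the default dataset."""
    params, networks, truth = default_dataset
    node_rows, global_rows = experiments.network_observation_table(networks)
    return node_rows, global_rows, truth
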