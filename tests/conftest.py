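import numpy as np
import pandas as pd
import pytest

from fcgraph import atlas, synth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def region_table():
    return atlas.load_region_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic cohort shared by pipeline/CLI tests."""
    cfg = synth.SimulationConfig(
        n_nodes=48, n_timepoints=60, n_motor=3, n_control=2,
        lesion_side_mode="right", scrub_range=(0, 0), seed=999)
    return synth.simulate_cohort(cfg)


def random_adjacency(rng, n, p):
    """Erdos-Renyi style symmetric 0/1 matrix with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


@pytest.fixture()
def random_adjacency_factory():
    return random_adjacency


@pytest.fixture()
def node_table_df():
    return pd.DataFrame({
        "node_id": [1, 2, 3, 4],
        "x": [-10.0, 9.0, 23.0, 0.0],
        "y": [-18.0, -4.0, 10.0, 5.0],
        "z": [7.0, 6.0, 1.0, 2.0],
    })
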