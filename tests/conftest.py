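import numpy as np
import pandas as pd
import pytest

from polyselect import synthetic


@pytest.fixture(scope="session")
def small_world():
    """A 250-species synthetic world shared across pipeline-level tests."""
    cfg = synthetic.WorldConfig(n_species=250, seed=11, n_trees=3)
    return synthetic.simulate_world(cfg)


@pytest.fixture(scope="session")
def small_world_dir(small_world, tmp_path_factory):
    d = tmp_path_factory.mktemp("world")
    synthetic.write_world(small_world, d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def lattice_cells():
    """Row/col frame for a full 15x15 lattice."""
    rows, cols = np.mgrid[0:15, 0:15]
    return pd.DataFrame({"row": rows.ravel(), "col": cols.ravel()})
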