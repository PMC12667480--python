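import numpy as np
import pytest

import tlscope as t


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated sample, shared across tests that only read it."""
    params = t.SimParams(seed=11)
    cells, counts, truth = t.simulate_sample(params, "S0")
    return params, cells, counts, truth


@pytest.fixture(scope="session")
def annotated_sim(default_sim):
    """Default sample carried through normalization, typing, and TLS calling."""
    params, cells, counts, truth = default_sim
    norm = t.lognormalize(counts)
    labels = t.assign_cell_types(norm)
    cells = cells.copy()
    cells["cell_type"] = cells["cell_id"].map(labels)
    regions = t.call_tls(cells)
    cells = t.assign_tls_membership(cells, regions)
    return params, cells, counts, truth, norm, regions


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
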