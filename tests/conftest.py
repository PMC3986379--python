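import numpy as np
import pandas as pd
import pytest

import bloodmix as bm


@pytest.fixture(scope="session")
def small_panel():
    """Compact 4-type reference panel with planted markers."""
    return bm.simulate_panel(K=4, p=120, markers_per_type=5, replicates=4, seed=7)


@pytest.fixture(scope="session")
def blood_panel():
    """Seven-type panel mimicking the leukocyte reference layout."""
    return bm.simulate_panel(K=7, p=800, markers_per_type=12, replicates=5, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_composition(n, cell_types, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(len(cell_types)), size=n)
    return bm.CompositionMatrix(
        pd.DataFrame(w, index=[f"s{i}" for i in range(n)], columns=cell_types)
    )
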