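import numpy as np
import pytest

from noisevolve import cytometry, synthetic_data


@pytest.fixture(scope="session")
def bead_table():
    return synthetic_data.simulate_beads(seed=11)


@pytest.fixture(scope="session")
def parental_table():
    return synthetic_data.simulate_parental(seed=12)


@pytest.fixture(scope="session")
def controls(parental_table, bead_table):
    return cytometry.estimate_controls(parental_table, bead_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
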