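import numpy as np
import pytest

from motifshape.simulate import SimulationConfig, make_pentamer_table


@pytest.fixture(scope="session")
def table():
    """One synthetic pentamer table shared across the suite."""
    return make_pentamer_table(SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
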