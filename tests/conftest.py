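import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def uniform_dna():
    from parsboot import uniform_cost

    return uniform_cost("dna")


@pytest.fixture
def titv():
    from parsboot import dna_titv_cost

    return dna_titv_cost()
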