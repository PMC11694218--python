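import numpy as np
import pytest

from crystalgp.fixtures import ToyPESParams, toy_monomer


@pytest.fixture(scope="session")
def pes_params():
    return ToyPESParams()


@pytest.fixture()
def water(pes_params):
    return toy_monomer(pes_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
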