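import numpy as np
import pytest

from dmdpep.peptide_model import Sequence, build_chain
from dmdpep.synthetic_data import ToyModelSpec, fixture_sequences, make_toy_system


@pytest.fixture(scope="session")
def sequences():
    return fixture_sequences()


@pytest.fixture()
def short_helix():
    """A 10-residue helical fragment (hIAPP 20-29) for engine tests."""
    return build_chain(Sequence("frag", "SNNFGAILSS"), "helix")


@pytest.fixture()
def dimer_toy():
    """Square-well dimer system plus its analytic reference model."""
    return make_toy_system(ToyModelSpec(kind="square_well_dimer"))


@pytest.fixture()
def two_level_toy():
    return make_toy_system(ToyModelSpec(kind="two_level", delta_e=1.4))[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
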