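"""Shared fixtures: packaged sequences and the assembled dimer model."""

import numpy as np
import pytest

from jiptandem import model_builder as mb
from jiptandem import synthetic_data as sd


@pytest.fixture(scope="session")
def sequences():
    return sd.fixture_sequences()


@pytest.fixture(scope="session")
def jip3(sequences):
    return sequences["JIP3"]


@pytest.fixture(scope="session")
def jip4(sequences):
    return sequences["JIP4"]


@pytest.fixture(scope="session")
def construct():
    """GSH + JIP3[22-187] expression construct (tag numbered 19-21)."""
    return sd.fixture_construct()


@pytest.fixture(scope="session")
def model(construct):
    """The assembled RH1-LZI dimer model (built once per session)."""
    return mb.assemble_rh1_lzi_dimer(construct)


@pytest.fixture(scope="session")
def model_curve(model):
    """Noiseless forward curve of the model on the default SWING-like grid."""
    return sd.simulate_curve(model, add_noise=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
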