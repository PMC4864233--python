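import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

import pmfdock as pk
from pmfdock.cgmap import BeadModel


@pytest.fixture(scope="session")
def synth_config():
    return pk.SynthConfig()


@pytest.fixture(scope="session")
def native(synth_config):
    return pk.make_native(synth_config)


@pytest.fixture(scope="session")
def bead_model(native):
    return pk.coarse_grain(native)


def light_pair_model(r=3.0, mass=1.0):
    """Two single-bead rigid groups: the cheapest dynamics test system."""
    return BeadModel(
        positions=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        masses=np.array([mass, mass]),
        types=np.array(["P", "P"]),
        charges=np.array([0, 0]),
        residue_index=np.array([0, 1]),
        groups=np.array(["receptor", "ligand"]),
    )


@pytest.fixture
def pair_model():
    return light_pair_model()
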