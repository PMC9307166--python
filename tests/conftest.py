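import numpy as np
import pytest

from magstimcal import coil_field as cf
from magstimcal import setup_calibration as sc

AMBIENT = (20.0, 5.0, -44.0)  # uT, a 49.2 uT earth-like background


@pytest.fixture(scope="session")
def exemplary_pairs():
    """The exemplary tri-axial square coil system (223/400/162 mm sides)."""
    return cf.exemplary_geometry_pairs()


@pytest.fixture(scope="session")
def physical_setup(exemplary_pairs):
    """Position-dependent setup model backed by Biot-Savart physics."""
    return sc.physical_setup(exemplary_pairs, [1.0, 1.0, 1.0], ambient=AMBIENT)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220722)
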