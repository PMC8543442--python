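import numpy as np
import pytest

from adlayers import load_vdw_radii
from adlayers.structures import AtomConfiguration, RadiusTable


@pytest.fixture(scope="session")
def radii():
    return load_vdw_radii()


@pytest.fixture(scope="session")
def carbon_radii():
    """Single-element table so probe reach is exactly R + 1.7 A."""
    return RadiusTable({"C": 1.7}, name="carbon-only")


def make_config(positions, elements=None, box=(20.0, 20.0, 20.0), **kw):
    positions = np.asarray(positions, dtype=float)
    if elements is None:
        elements = ["C"] * len(positions)
    return AtomConfiguration(positions, elements, np.asarray(box, float), **kw)


@pytest.fixture
def config_factory():
    return make_config
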