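import numpy as np
import pytest

from chemomech import PillarGeometry


@pytest.fixture
def paper_geometry() -> PillarGeometry:
    """PDMS pillar geometry: D=0.5 µm, L=1.8 µm, E=2 MPa, 1 µm pitch."""
    return PillarGeometry(diameter=0.5, height=1.8, youngs_modulus=2.0, pitch=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
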