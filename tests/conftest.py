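"""Shared fixtures: small grids and the (expensive) default phantom."""

import numpy as np
import pytest

from artqa.core import VoxelGrid
from artqa.criteria import default_criteria, filter_to_available
from artqa.simulate import build_phantom


@pytest.fixture
def small_grid():
    """1-mm isotropic 12x12x6 grid for exhaustive oracles."""
    return VoxelGrid((12, 12, 6), (0.1, 0.1, 0.1))


@pytest.fixture(scope="session")
def phantom():
    """The default neck phantom; built once per session."""
    return build_phantom()


@pytest.fixture(scope="session")
def phantom_criteria(phantom):
    return filter_to_available(default_criteria(), phantom.structures.names)


@pytest.fixture(scope="session")
def phantom_specs(phantom_criteria):
    return [c.parameter_spec() for c in phantom_criteria]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
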