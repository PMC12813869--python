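import numpy as np
import pytest

import sfrtplan as sp


@pytest.fixture(scope="session")
def reference_plan():
    """The deterministic reference lattice plan (built once per session)."""
    return sp.reference_lattice_plan()


@pytest.fixture(scope="session")
def small_grid():
    """A 41^3 1 mm grid centered on the origin."""
    return sp.VoxelGrid.centered((20, 20, 20))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def sphere_of_volume(grid, volume_cc, name="GTV"):
    radius = (3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return sp.sphere_mask(grid, (0, 0, 0), radius, name)
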