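"""Shared fixtures: one default synthetic head, a 30 mm on-scalp array and
the dense reference lead field, built once per session."""

import numpy as np
import pytest

from opmarray.arrays import offset_array, pack_sensors
from opmarray.forward import build_leadfield
from opmarray.geometry import assign_parcels, make_cortex, make_scalp, select_sources


@pytest.fixture(scope="session")
def scalp():
    return make_scalp(90.0, 2562, seed=1)


@pytest.fixture(scope="session")
def space(scalp):
    return assign_parcels(make_cortex(scalp, seed=2), 90, seed=3)


@pytest.fixture(scope="session")
def sources(space):
    return select_sources(space, 20, 20)


@pytest.fixture(scope="session")
def z_floor(space):
    return float(space.mesh.vertices[:, 2].min())


@pytest.fixture(scope="session")
def array30(scalp, z_floor):
    """~30 mm spacing on-scalp (6.5 mm standoff) array."""
    return offset_array(pack_sensors(scalp, 30.0, z_floor_mm=z_floor, seed=4), 6.5)


@pytest.fixture(scope="session")
def dense_array(scalp, z_floor):
    """Dense on-scalp reference array (~700 potential sensor positions)."""
    return offset_array(pack_sensors(scalp, 11.5, z_floor_mm=z_floor, seed=5), 6.5)


@pytest.fixture(scope="session")
def dense_lf(space, dense_array):
    """Dense lead field: all cortex sources x dense reference sensors."""
    return build_leadfield(space, dense_array)


@pytest.fixture(scope="session")
def small_dense_lf(space, scalp, z_floor):
    """Coarse dense lead field for optimisation-heavy tests: ~230 sensors
    over a quarter of the source space."""
    arr = offset_array(pack_sensors(scalp, 20.0, z_floor_mm=z_floor, seed=6), 6.5)
    src = np.arange(0, space.n_vertices, 4)
    return build_leadfield(space, arr, source_indices=src)
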