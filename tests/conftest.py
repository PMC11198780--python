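import numpy as np
import pytest

from cephalo3d.hourglass3d import NetworkConfig
from cephalo3d.imaging_io import LandmarkSet, Volume
from cephalo3d.phantom import full46_spec, full46_template, toy8_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20240625)


@pytest.fixture
def small_volume():
    """A 20^3 anisotropic volume with a linear-ramp intensity field."""
    shape = (20, 20, 20)
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    data = 1.0 * grids[0] + 0.5 * grids[1] - 0.25 * grids[2]
    return Volume(data, spacing=(0.4, 0.4, 0.6), origin=(5.0, -3.0, 2.0))


@pytest.fixture
def toy_net_config():
    """Small hourglass that trains on a CPU in seconds."""
    return NetworkConfig(
        out_channels=8, stem_features=8, block_features=(8, 8, 16), gn_groups=4,
        depth=2, seed=0,
    )


@pytest.fixture
def full46_landmarks():
    """The canonical 46-landmark template as a LandmarkSet."""
    from cephalo3d.cephalometrics import schema_id_list

    return LandmarkSet(full46_template(), tuple(schema_id_list()))


@pytest.fixture
def toy_spec():
    return toy8_spec(seed=7)
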