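import numpy as np
import pytest

import hemiasym as ha
from hemiasym.volume import VolumeGrid, mni_grid


@pytest.fixture(scope="session")
def catalog():
    return ha.default_catalog()


def identity_grid(shape=(9, 9, 9)):
    """A tiny grid whose voxel indices coincide with mm coordinates."""
    return VolumeGrid(data=np.zeros(shape), affine=np.eye(4))


@pytest.fixture(scope="session")
def coarse_cfg():
    """A small, fast cohort: 6 subjects on a 6-mm MNI-like grid."""
    return ha.CohortConfig(
        n_young=3, n_old=3, grid_shape=(31, 37, 31), voxel_size=6.0, seed=11
    )


@pytest.fixture(scope="session")
def coarse_cohort(coarse_cfg):
    return ha.generate_cohort(coarse_cfg)


@pytest.fixture(scope="session")
def coarse_grid():
    return mni_grid(shape=(31, 37, 31), voxel_size=6.0)
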