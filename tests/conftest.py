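import numpy as np
import pytest
from hypothesis import settings

import cuetopo as ct

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mixture():
    """The three-component frontal mixture the analysis targets."""
    return ct.DEFAULT_MIXTURE


@pytest.fixture
def small_grid():
    """5x5x5 grid, 3 mm isotropic, RAS with a frontal-ish origin."""
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = [-6.0, -6.0, -6.0]
    return ct.VolumeGrid(np.zeros((5, 5, 5)), affine)


@pytest.fixture
def unit_mask():
    def make(shape=(12, 12, 12), voxel_mm=3.0):
        affine = np.diag([voxel_mm] * 3 + [1.0])
        return ct.MaskVolume(ct.VolumeGrid(np.ones(shape), affine))
    return make
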