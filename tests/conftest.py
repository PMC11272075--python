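import numpy as np
import pytest

from voxnmf import synthetic
from voxnmf.imaging_io import MaskedGrid


@pytest.fixture(scope="session")
def small_grid() -> MaskedGrid:
    """~550-voxel ellipsoidal mask in a 12^3 grid."""
    return synthetic.default_grid(12)


@pytest.fixture(scope="session")
def tiny_grid() -> MaskedGrid:
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1:3, 1:3, 1:3] = True
    return MaskedGrid.from_mask(mask)


@pytest.fixture(scope="session")
def planted3(small_grid):
    """Noiseless rank-3 cohort with known dictionary and loads."""
    D = synthetic.generate_components(small_grid, 3, seed=1)
    X, clinical, truth = synthetic.generate_cohort(D, 30, small_grid, noise_sd=0.0, seed=2)
    return X, clinical, truth
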