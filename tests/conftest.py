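import numpy as np
import pytest

from scenersa.gist import build_filterbank
from scenersa.synthetic_data import generate_voxel_dataset


@pytest.fixture(scope="session")
def bank64():
    return build_filterbank(size=64)


@pytest.fixture(scope="session")
def random_model_matrix():
    """A plausible 10x10 correlation-structure model matrix."""
    rng = np.random.default_rng(7)
    return np.corrcoef(rng.standard_normal((10, 6)))


@pytest.fixture(scope="session")
def voxel_dataset(random_model_matrix):
    """8 subjects x 10 conditions x 2000 voxels with planted structure."""
    return generate_voxel_dataset(8, 10, 2000, random_model_matrix,
                                  signal_sd=1.0, noise_sd=1.0, seed=11)
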