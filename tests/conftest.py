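import numpy as np
import pytest

from kinquant.segmentation import SegmentationParams
from kinquant.simulate import SimImageParams


@pytest.fixture
def seg_params():
    return SegmentationParams()


@pytest.fixture
def small_params():
    """A fast-but-realistic synthetic cell: 3 pairs, spots large enough to
    clear the default 70-voxel minimum object size."""
    return SimImageParams(
        grid_dims=(16, 72, 72),
        n_pairs=3,
        sigma_xy_um=0.15,
        sigma_z_um=0.40,
        amplitude_mean={"ACA": 5e4, "target": 5e4},
        nuclear_semiaxes_um=(1.1, 2.2, 2.2),
        seed=0,
    )


@pytest.fixture
def noiseless_params(small_params):
    from dataclasses import replace

    return replace(small_params, shot_noise=False, read_noise_sd=0.0, amplitude_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
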