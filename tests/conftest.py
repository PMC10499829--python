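import numpy as np
import pytest

import deeptfm as d
from deeptfm import scatter_mc as mc


@pytest.fixture(scope="session")
def ex_psf():
    return d.make_gaussian_psf(1.0, 1.036, 1.33, (9, 15, 15), (1, 1, 1), "excitation")


@pytest.fixture(scope="session")
def em_psf():
    return d.make_gaussian_psf(1.0, 0.58, 1.33, (9, 15, 15), (1, 1, 1), "emission")


@pytest.fixture(scope="session")
def bead_volume():
    return d.generate_beads_volume(
        d.BeadSpec(seed=11, n_small=3, n_large=2), (9, 48, 48)
    )


def delta_spsf(n_planes: int, shape=(15, 15)) -> mc.ScatteringPSFStack:
    """An sPSF stack of discrete deltas (no scattering) for reduction tests."""
    img = np.zeros(shape)
    img[(shape[0] - 1) // 2, (shape[1] - 1) // 2] = 1.0
    return mc.ScatteringPSFStack(
        images=np.stack([img] * n_planes),
        depths=np.arange(n_planes, dtype=float),
        pixel_size=1.0,
        acceptance=np.ones(n_planes),
        photons_launched=1,
    )


@pytest.fixture(scope="session")
def small_camera():
    return d.CameraModel(g_em=50.0, n_stages=256, dark_mean=0.1,
                         read_sigma=5.0, lut_max_input=40)


@pytest.fixture(scope="session")
def small_lut(small_camera):
    return d.build_em_lut(small_camera, n_draws=4000, pool_size=40000, seed=7)
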