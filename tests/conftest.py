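"""Shared fixtures: small geometries, volumes and noisy acquisitions."""

import numpy as np
import pytest

from tomomdr.geometry import (ScanGeometry, SystemProjector, VolumeSpec,
                              gaussian_blur_kernel, pristina_like)
from tomomdr.noise import NoiseModel, SinogramStack, simulate_measurement


@pytest.fixture
def rng():
    """Fresh deterministic generator per test (order-independent draws)."""
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_vol():
    return VolumeSpec(shape=(8, 8, 4))


@pytest.fixture(scope="session")
def small_geom():
    return pristina_like(detector_shape=(16, 24))


@pytest.fixture(scope="session")
def small_projector(small_geom, small_vol):
    return SystemProjector(small_geom, small_vol)


@pytest.fixture(scope="session")
def noise_model():
    return NoiseModel(sigma_q=0.05, sigma_r=0.01,
                      blur=gaussian_blur_kernel(2.0))


@pytest.fixture(scope="session")
def toy_scene(noise_model):
    """16x16x1 grid, 9 views, noisy acquisition of a smooth random volume."""
    vol = VolumeSpec(shape=(16, 16, 1))
    geom = pristina_like(detector_shape=(24, 32))
    proj = SystemProjector(geom, vol)
    g = np.random.default_rng(7)
    x_true = g.normal(size=vol.shape) * 0.02 + 0.05
    views = np.stack([
        simulate_measurement(proj.project(x_true, i), noise_model, 100 + i)
        for i in range(geom.n_views)])
    sino = SinogramStack(views=views, geom=geom, noise=noise_model)
    return dict(vol=vol, geom=geom, proj=proj, x_true=x_true, sino=sino)


class IdentityProjector:
    """A = I toy operator: detector grid equals the (nx, ny) of a 1-slice
    volume."""

    def __init__(self, shape=(4, 4), n_views=1):
        self.shape = shape
        self.n_views = n_views

    def project(self, x, i):
        return np.asarray(x)[:, :, 0].copy()

    def backproject(self, y, i):
        return np.asarray(y)[:, :, None].copy()

    def row_sums(self, i):
        return np.ones(self.shape)

    def column_sums(self, i):
        return np.ones(self.shape + (1,))

    def in_field_mask(self):
        return np.ones(self.shape + (1,), dtype=bool)


@pytest.fixture
def identity_projector():
    return IdentityProjector()
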