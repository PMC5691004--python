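import numpy as np
import pytest

from cbctshade import (CorrectionConfig, CTVolume, Insert, PhantomSpec,
                       Unit, make_phantom)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume():
    """16x16x4 all-zero HU volume."""
    return CTVolume(values=np.zeros((4, 16, 16)), unit=Unit.HU,
                    spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def fast_cfg():
    """Coarse polar grid so per-slice processing stays fast in unit tests."""
    return CorrectionConfig(n_radial=200, n_angular=180, downsample_factor=1)


def make_disk_slice(n=128, radius=40.0, inside=0.0, outside=-1000.0,
                    center=None):
    cy = cx = (n - 1) / 2.0
    if center is not None:
        cx, cy = center
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - cy, xx - cx)
    return np.where(r <= radius, inside, outside).astype(float)


@pytest.fixture
def desk_phantom():
    """Small body-only phantom for pipeline unit tests (8 slices, 128^2)."""
    spec = PhantomSpec(grid_shape=(8, 128, 128), spacing=(2.8, 2.8, 2.8),
                      body_semi_axes_mm=(150.0, 110.0))
    return make_phantom(spec)


@pytest.fixture
def insert_phantom():
    """Phantom with bone, gas, and a low-contrast insert."""
    spec = PhantomSpec(
        grid_shape=(8, 128, 128), spacing=(2.8, 2.8, 2.8),
        body_semi_axes_mm=(150.0, 110.0),
        inserts=(
            Insert(shape="ellipse", hu=300.0, center_mm=(60.0, 20.0),
                   size_mm=(18.0, 14.0)),
            Insert(shape="ellipse", hu=-600.0, center_mm=(-55.0, -25.0),
                   size_mm=(20.0, 16.0)),
            Insert(shape="box", hu=50.0, center_mm=(0.0, 45.0),
                   size_mm=(15.0, 12.0)),
        ))
    return make_phantom(spec)
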