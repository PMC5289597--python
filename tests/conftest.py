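import numpy as np
import pytest

from vesel.foreground import BinaryStack
from vesel.io_formats import TomogramStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_stack(voxels, px=1.0, dz=1.0):
    return TomogramStack(
        voxels=np.asarray(voxels, dtype=np.float32), px_size_xy=px,
        voxel_depth_z=dz,
    )


def make_binary(mask, px=1.0, dz=1.0):
    return BinaryStack(np.asarray(mask, dtype=bool), px, dz)


def digitize_ball(radius, shape=None, center=None, dz=1.0):
    """Boolean (z, y, x) mask of voxel centers inside a physical ball."""
    if shape is None:
        n = int(np.ceil(2 * radius)) + 5
        shape = (int(np.ceil(2 * radius / dz)) + 5, n, n)
    nz, ny, nx = shape
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) * dz / 2.0)
    cx, cy, cz = center
    zz = np.arange(nz) * dz - cz
    yy = np.arange(ny) - cy
    xx = np.arange(nx) - cx
    d2 = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    return d2 < radius**2


@pytest.fixture(scope="session")
def small_phantom():
    """Small noisy phantom shared by slower integration tests."""
    from vesel.phantom import PhantomParams, generate_phantom

    params = PhantomParams(
        shape_vx=(36, 160, 160), n_vesicles=5, n_confounders=0, seed=7,
        inner_diam_mean_nm=34.0, inner_diam_sd_nm=3.0,
    )
    stack, gt, roi_first, roi_last = generate_phantom(params)
    return params, stack, gt, roi_first, roi_last
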