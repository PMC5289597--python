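"""Preprocessing stage: xy rescale to 1 nm/px, global contrast stretch,
per-slice mean filtering and per-slice bilateral filtering.

Filters run slice-wise in 2D; only :func:`rescale_xy` changes stack
dimensions, and it never touches z.  Every filter output lies within
the [min, max] range of its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "PreprocessParams",
    "rescale_xy",
    "stretch_contrast",
    "mean_filter",
    "bilateral_filter",
    "disk_offsets",
    "run_preprocess",
]


@dataclass
class PreprocessParams:
    target_px_nm: float = 1.0
    saturation_fraction: float = 0.004
    mean_radius_px: float = 3.45
    bilateral_spatial_sigma: float = 3.0
    bilateral_range_sigma: float = 50.0

    def __post_init__(self):
        if self.target_px_nm <= 0:
            raise ValueError("target_px_nm must be positive")
        if not 0 <= self.saturation_fraction < 0.5:
            raise ValueError("saturation_fraction must be in [0, 0.5)")
        if self.mean_radius_px <= 0:
            raise ValueError("mean_radius_px must be positive")


def disk_offsets(radius):
    """Integer (dy, dx) offsets with dy^2 + dx^2 <= radius^2."""
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return dy[keep], dx[keep]


def disk_kernel(radius, normalized=True):
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    k = (dy * dy + dx * dx <= radius * radius).astype(float)
    if normalized:
        k /= k.sum()
    return k


def rescale_xy(stack, params=None):
    """Resample each slice to ``target_px_nm`` with bilinear interpolation.

    z dimension and voxel depth are unchanged.
    """
    params = params or PreprocessParams()
    factor = stack.px_size_xy / params.target_px_nm
    if abs(factor - 1.0) < 1e-12:
        return stack.with_voxels(stack.voxels.copy(), px_size_xy=params.target_px_nm)
    nz, ny, nx = stack.shape
    out_y = max(1, int(round(ny * factor)))
    out_x = max(1, int(round(nx * factor)))
    out = np.empty((nz, out_y, out_x), dtype=np.float32)
    for z in range(nz):
        out[z] = ndi.zoom(
            stack.voxels[z].astype(np.float32),
            (out_y / ny, out_x / nx),
            order=1,
            mode="nearest",
            grid_mode=True,
        )
    return stack.with_voxels(out, px_size_xy=params.target_px_nm)


def stretch_contrast(stack, params=None):
    """Histogram stretch over the whole stack onto [0, 255].

    Clip points are the ``saturation_fraction / 2`` and
    ``1 - saturation_fraction / 2`` empirical quantiles of all voxels;
    values are affine-mapped so low -> 0 and high -> 255 and clipped.
    Constant stacks are returned unchanged.
    """
    params = params or PreprocessParams()
    v = stack.voxels.astype(np.float64)
    half = params.saturation_fraction / 2.0
    low, high = np.quantile(v, [half, 1.0 - half])
    if high <= low:
        return stack.with_voxels(stack.voxels.copy())
    out = (v - low) * (255.0 / (high - low))
    np.clip(out, 0.0, 255.0, out=out)
    return stack.with_voxels(out.astype(np.float32))


def mean_filter(stack, params=None):
    """Per-slice mean filter with a flat circular kernel (edge replication)."""
    params = params or PreprocessParams()
    kernel = disk_kernel(params.mean_radius_px)
    out = np.empty_like(stack.voxels, dtype=np.float32)
    for z in range(stack.shape[0]):
        out[z] = ndi.convolve(
            stack.voxels[z].astype(np.float32), kernel, mode="nearest"
        )
    return stack.with_voxels(out)


def _bilateral_slice(img, spatial_sigma, range_sigma, radius):
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = dy * dy + dx * dx <= radius * radius
    offsets = np.stack([dy[keep], dx[keep]], axis=1)
    spatial_w = np.exp(
        -(offsets[:, 0] ** 2 + offsets[:, 1] ** 2) / (2.0 * spatial_sigma**2)
    )
    padded = np.pad(img, radius, mode="edge")
    h, w = img.shape
    acc = np.zeros((h, w), dtype=np.float64)
    norm = np.zeros((h, w), dtype=np.float64)
    inv2rs2 = 1.0 / (2.0 * range_sigma**2)
    for (oy, ox), sw in zip(offsets, spatial_w):
        shifted = padded[radius + oy : radius + oy + h, radius + ox : radius + ox + w]
        rw = np.exp(-((shifted - img) ** 2) * inv2rs2)
        w_tot = sw * rw
        acc += w_tot * shifted
        norm += w_tot
    return acc / norm


def bilateral_filter(stack, params=None):
    """Per-slice bilateral smoothing: spatial Gaussian x intensity Gaussian.

    The window radius is 2 spatial sigmas.  Output is a weighted mean of
    window values, hence bounded by the local input min/max.
    """
    params = params or PreprocessParams()
    if params.bilateral_spatial_sigma <= 0 or params.bilateral_range_sigma <= 0:
        raise ValueError("bilateral sigmas must be positive")
    radius = max(1, int(np.ceil(2.0 * params.bilateral_spatial_sigma)))
    out = np.empty_like(stack.voxels, dtype=np.float32)
    for z in range(stack.shape[0]):
        out[z] = _bilateral_slice(
            stack.voxels[z].astype(np.float64),
            params.bilateral_spatial_sigma,
            params.bilateral_range_sigma,
            radius,
        )
    return stack.with_voxels(out)


def run_preprocess(stack, params=None):
    """Fixed pipeline order: rescale -> stretch -> mean -> bilateral."""
    params = params or PreprocessParams()
    out = rescale_xy(stack, params)
    out = stretch_contrast(out, params)
    out = mean_filter(out, params)
    out = bilateral_filter(out, params)
    return out
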