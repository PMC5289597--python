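"""Foreground separation: per-slice mean thresholding, cell-region
masking via slice-interpolated polygon ROIs, and bounded hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .io_formats import PolygonRoi

__all__ = [
    "BinaryStack",
    "RoiSeries",
    "HoleFillParams",
    "threshold_mean",
    "interpolate_roi",
    "apply_roi_mask",
    "fill_holes_bounded",
    "points_in_polygon",
]


@dataclass
class BinaryStack:
    """Boolean foreground mask in (z, y, x) order with calibration."""

    mask: np.ndarray
    px_size_xy: float
    voxel_depth_z: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")

    @property
    def shape(self):
        return self.mask.shape

    def with_mask(self, mask):
        return BinaryStack(mask, self.px_size_xy, self.voxel_depth_z)


@dataclass
class RoiSeries:
    """One closed polygon per slice, covering every z index of a stack."""

    polygons: list

    def __post_init__(self):
        for i, poly in enumerate(self.polygons):
            if poly.slice_index != i:
                raise ValueError(
                    f"polygon {i} has slice_index {poly.slice_index}"
                )

    def __len__(self):
        return len(self.polygons)

    def __getitem__(self, i):
        return self.polygons[i]


@dataclass
class HoleFillParams:
    dilation_radius_px: int = 1
    hole_min_px: int = 0
    hole_max_px: int = 575

    def __post_init__(self):
        if not 0 <= self.hole_min_px <= self.hole_max_px:
            raise ValueError("need 0 <= hole_min_px <= hole_max_px")
        if self.dilation_radius_px < 0:
            raise ValueError("dilation_radius_px must be >= 0")


def threshold_mean(stack, polarity="dark"):
    """Per-slice threshold at the slice mean intensity.

    polarity="dark" selects pixels strictly below the slice mean
    (electron-dense structures); polarity="bright" selects pixels
    strictly above it (membrane-bounded lumina on a darker, granular
    field).  A constant slice yields an empty foreground either way.
    """
    if polarity not in ("dark", "bright"):
        raise ValueError(f"unknown polarity {polarity!r}")
    v = stack.voxels
    means = v.mean(axis=(1, 2), keepdims=True)
    mask = v < means if polarity == "dark" else v > means
    return BinaryStack(mask, stack.px_size_xy, stack.voxel_depth_z)


# ---------------------------------------------------------------------------
# ROI interpolation

def _ensure_ccw(verts):
    x, y = verts[:, 0], verts[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return verts if area2 > 0 else verts[::-1].copy()


def _anchor_to_max_x(verts):
    """Rotate the vertex cycle so it starts at the max-x (then max-y) vertex."""
    idx = np.lexsort((verts[:, 1], verts[:, 0]))[-1]
    return np.roll(verts, -idx, axis=0)


def resample_polygon(verts, n_points=128):
    """Resample a closed polygon to ``n_points`` by uniform arc length,
    starting at vertex 0."""
    closed = np.vstack([verts, verts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate polygon with zero perimeter")
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    xs = np.interp(targets, cum, closed[:, 0])
    ys = np.interp(targets, cum, closed[:, 1])
    return np.stack([xs, ys], axis=1)


def interpolate_roi(first, last, n_slices, n_points=128):
    """Linear vertex-wise blend of two boundary polygons across all slices.

    Both polygons are oriented counterclockwise, anchored at their
    maximal-x vertex and resampled to a common vertex count before
    blending with weight z / (n_slices - 1).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if n_slices == 1:
        verts = resample_polygon(
            _anchor_to_max_x(_ensure_ccw(first.vertices)), n_points
        )
        return RoiSeries([PolygonRoi(0, verts)])
    if first.slice_index != 0 or last.slice_index != n_slices - 1:
        raise ValueError(
            "first polygon must be on slice 0 and last on slice n_slices - 1"
        )
    a = resample_polygon(_anchor_to_max_x(_ensure_ccw(first.vertices)), n_points)
    b = resample_polygon(_anchor_to_max_x(_ensure_ccw(last.vertices)), n_points)
    polys = []
    for z in range(n_slices):
        w = z / (n_slices - 1)
        polys.append(PolygonRoi(z, (1.0 - w) * a + w * b))
    return RoiSeries(polys)


def points_in_polygon(px, py, verts):
    """Even-odd (crossing number) point-in-polygon test, vectorized.

    Half-open edge convention: a point on the left/bottom boundary of an
    axis-aligned box counts as inside, on the right/top as outside, so a
    w x h axis-aligned rectangle contains exactly w * h pixel centers.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cond = (y1 > py) != (y2 > py)
        if not np.any(cond):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        crossing = cond & (px < xint)
        inside ^= crossing
    return inside


def polygon_mask(verts, shape):
    """Boolean (ny, nx) mask of pixel centers inside the polygon."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    return points_in_polygon(xx, yy, np.asarray(verts, dtype=float))


def apply_roi_mask(binary, rois):
    """Zero out foreground outside each slice's polygon (pixel-center test)."""
    if len(rois) != binary.shape[0]:
        raise ValueError(
            f"RoiSeries has {len(rois)} polygons for {binary.shape[0]} slices"
        )
    out = binary.mask.copy()
    for z in range(binary.shape[0]):
        out[z] &= polygon_mask(rois[z].vertices, binary.shape[1:])
    return binary.with_mask(out)


# ---------------------------------------------------------------------------
# bounded hole filling

_STRUCT_4 = ndi.generate_binary_structure(2, 1)


def _fill_holes_slice(mask2d, hole_min, hole_max):
    bg_labels, n = ndi.label(~mask2d, structure=_STRUCT_4)
    if n == 0:
        return mask2d
    border = np.zeros_like(mask2d, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = np.unique(bg_labels[border & (bg_labels > 0)])
    areas = np.bincount(bg_labels.ravel(), minlength=n + 1)
    fill_ids = np.ones(n + 1, dtype=bool)
    fill_ids[0] = False
    fill_ids[touching] = False
    fill_ids &= (areas >= hole_min) & (areas <= hole_max)
    if not fill_ids.any():
        return mask2d
    return mask2d | fill_ids[bg_labels]


def fill_holes_bounded(binary, params=None):
    """Per slice: dilate, then fill enclosed background components whose
    pixel area lies in [hole_min_px, hole_max_px].

    A hole is a 4-connected background component not touching the slice
    border.  Larger holes are left untouched.  The dilation is not
    undone; the output is the dilated, hole-filled mask.
    """
    params = params or HoleFillParams()
    out = np.empty_like(binary.mask)
    footprint = disk(params.dilation_radius_px) if params.dilation_radius_px else None
    for z in range(binary.shape[0]):
        m = binary.mask[z]
        if footprint is not None:
            m = ndi.binary_dilation(m, structure=footprint)
        out[z] = _fill_holes_slice(m, params.hole_min_px, params.hole_max_px)
    return binary.with_mask(out)
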