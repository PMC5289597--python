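"""Image-stack, polygon-ROI, label-map and result-table I/O.

All volumes are held in (z, y, x) axis order with physical calibration
attached: ``px_size_xy`` nm per pixel in x and y, ``voxel_depth_z`` nm
per slice.  File coordinates are 0-based with x = column, y = row.
Lengths in result tables are nanometres throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

from . import _mrc

__all__ = [
    "TomogramStack",
    "PolygonRoi",
    "LabelStack",
    "VesicleRecord",
    "StackFormatError",
    "read_stack",
    "write_stack",
    "read_polygon_roi",
    "write_polygon_roi",
    "read_labels",
    "write_labels",
    "results_columns",
    "write_results",
    "read_results",
]

RESULT_BASE_COLUMNS = [
    "label",
    "center_x_nm",
    "center_y_nm",
    "center_z_nm",
    "volume_nm3",
    "feret_nm",
    "diam1_nm",
    "diam2_nm",
    "diam3_nm",
    "mean_diam_nm",
    "corrected_diam_nm",
    "sphericity",
    "elongation",
]


class StackFormatError(ValueError):
    """Raised for unreadable or unsupported image-stack files."""


def _validate_calibration(px_size_xy, voxel_depth_z):
    if not (px_size_xy > 0 and np.isfinite(px_size_xy)):
        raise ValueError(f"px_size_xy must be positive, got {px_size_xy}")
    if not (voxel_depth_z > 0 and np.isfinite(voxel_depth_z)):
        raise ValueError(f"voxel_depth_z must be positive, got {voxel_depth_z}")


@dataclass
class TomogramStack:
    """3D intensity volume with physical calibration.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar intensities, converted to float on load.
    px_size_xy : float
        nm per pixel in x and y.
    voxel_depth_z : float
        nm per slice in z.
    source_path : str
        Provenance string (empty for in-memory stacks).
    """

    voxels: np.ndarray
    px_size_xy: float
    voxel_depth_z: float
    source_path: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("stack must be 3D (z, y, x)")
        if min(self.voxels.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        _validate_calibration(self.px_size_xy, self.voxel_depth_z)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack intensities must be finite")

    @property
    def shape(self):
        return self.voxels.shape

    def with_voxels(self, voxels, px_size_xy=None):
        """Copy of this stack with new voxel data (and optionally new xy scale)."""
        return replace(
            self,
            voxels=voxels,
            px_size_xy=self.px_size_xy if px_size_xy is None else px_size_xy,
        )


@dataclass
class PolygonRoi:
    """Closed polygon on one slice; vertices are (x, y) pixel coordinates."""

    slice_index: int
    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if abs(self.signed_area()) <= 0:
            raise ValueError("polygon has zero area")

    def signed_area(self):
        x = self.vertices[:, 0]
        y = self.vertices[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def area(self):
        return abs(self.signed_area())


@dataclass
class LabelStack:
    """Integer-labeled volume: 0 = background, k > 0 = candidate k."""

    labels: np.ndarray
    px_size_xy: float
    voxel_depth_z: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z, y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        _validate_calibration(self.px_size_xy, self.voxel_depth_z)

    @property
    def shape(self):
        return self.labels.shape

    def ids(self):
        out = np.unique(self.labels)
        return out[out > 0]


@dataclass
class VesicleRecord:
    """Per-candidate morphometry; all lengths in nm, volumes in nm^3."""

    label: int
    center_nm: tuple  # (x, y, z)
    volume_nm3: float
    volume_vx: int
    surface_nm2: float
    feret_nm: float
    diam_nm: tuple  # (d1, d2, d3), descending
    sphericity: float
    elongation: float
    mean_diam_nm: float = float("nan")
    corrected_diam_nm: float = float("nan")
    nn_dists_nm: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# image stacks

def read_stack(path, px_size_xy=None, voxel_depth_z=None):
    """Read an MRC (mode 0/1/2) or multi-page TIFF stack.

    The MRC header voxel size is used as the default calibration when
    present; explicit ``px_size_xy`` / ``voxel_depth_z`` (nm) override it.
    TIFF files carry no trusted calibration here, so both values are
    required for TIFF input.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise StackFormatError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    header_px = header_dz = None
    if ext in (".mrc", ".map", ".rec", ".st"):
        try:
            data, voxel_ang = _mrc.read_mrc(path)
        except _mrc.MrcFormatError as exc:
            raise StackFormatError(str(exc)) from exc
        # MRC cell spacing is in angstrom: 10 A = 1 nm
        if voxel_ang[0] > 0:
            header_px = voxel_ang[0] / 10.0
        if voxel_ang[2] > 0:
            header_dz = voxel_ang[2] / 10.0
    elif ext in (".tif", ".tiff"):
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # tifffile raises several error types
            raise StackFormatError(f"cannot read TIFF {path}: {exc}") from exc
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise StackFormatError(
                f"{path}: expected a grayscale stack, got shape {data.shape}"
            )
    else:
        raise StackFormatError(f"{path}: unsupported extension {ext!r}")

    px = px_size_xy if px_size_xy is not None else header_px
    dz = voxel_depth_z if voxel_depth_z is not None else header_dz
    if px is None or dz is None:
        raise ValueError(
            f"{path}: calibration (px_size_xy, voxel_depth_z) required"
        )
    return TomogramStack(
        voxels=np.asarray(data, dtype=np.float32),
        px_size_xy=float(px),
        voxel_depth_z=float(dz),
        source_path=path,
    )


def write_stack(path, stack, dtype=None):
    """Write a TomogramStack as MRC (mode 2 by default) or multi-page TIFF."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    data = stack.voxels if dtype is None else stack.voxels.astype(dtype)
    if ext in (".mrc", ".map", ".rec", ".st"):
        px_ang = stack.px_size_xy * 10.0
        dz_ang = stack.voxel_depth_z * 10.0
        _mrc.write_mrc(path, data, voxel_size=(px_ang, px_ang, dz_ang))
    elif ext in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(data), photometric="minisblack")
    else:
        raise StackFormatError(f"{path}: unsupported extension {ext!r}")


# ---------------------------------------------------------------------------
# polygon ROI files

def read_polygon_roi(path):
    """Read the plain-text ROI format: ``slice <i>`` then one ``x y`` per line."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines or not lines[0].lower().startswith("slice"):
        raise ValueError(f"{path}: first line must be 'slice <index>'")
    try:
        slice_index = int(lines[0].split()[1])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed slice line {lines[0]!r}") from exc
    verts = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed vertex line {ln!r}")
        verts.append((float(parts[0]), float(parts[1])))
    return PolygonRoi(slice_index=slice_index, vertices=np.array(verts))


def write_polygon_roi(path, roi):
    with open(path, "w") as fh:
        fh.write(f"slice {roi.slice_index}\n")
        for x, y in roi.vertices:
            fh.write(f"{x:.6g} {y:.6g}\n")


# ---------------------------------------------------------------------------
# label maps

def write_labels(path, labels):
    """Write a LabelStack as 16-bit (or 32-bit when needed) multi-page TIFF."""
    arr = labels.labels
    if arr.size and arr.max() > np.iinfo(np.uint16).max:
        out = arr.astype(np.uint32)
    else:
        out = arr.astype(np.uint16)
    tifffile.imwrite(os.fspath(path), out, photometric="minisblack")


def read_labels(path, px_size_xy, voxel_depth_z):
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim == 2:
        arr = arr[None]
    return LabelStack(
        labels=arr.astype(np.int32),
        px_size_xy=float(px_size_xy),
        voxel_depth_z=float(voxel_depth_z),
    )


# ---------------------------------------------------------------------------
# result tables

def results_columns(n_neighbors):
    return RESULT_BASE_COLUMNS + [
        f"dist_nn{i}_nm" for i in range(1, n_neighbors + 1)
    ]


def _record_row(rec, n_neighbors):
    d1, d2, d3 = rec.diam_nm
    row = [
        rec.label,
        rec.center_nm[0],
        rec.center_nm[1],
        rec.center_nm[2],
        rec.volume_nm3,
        rec.feret_nm,
        d1,
        d2,
        d3,
        rec.mean_diam_nm,
        rec.corrected_diam_nm,
        rec.sphericity,
        rec.elongation,
    ]
    dists = list(rec.nn_dists_nm)
    dists = dists[:n_neighbors] + [float("nan")] * (n_neighbors - len(dists))
    return row + dists


def write_results(records, path, n_neighbors=None):
    """Write vesicle records as RFC-4180 CSV (one row per vesicle).

    Column count is 13 + n for neighbor count n; missing neighbor
    distances are written as empty fields.
    """
    if n_neighbors is None:
        n_neighbors = max((len(r.nn_dists_nm) for r in records), default=0)
    counts = {len(r.nn_dists_nm) for r in records}
    if counts and counts != {n_neighbors} and counts != {0}:
        extra = counts - {n_neighbors}
        if extra and max(extra) > n_neighbors:
            raise ValueError(
                f"inconsistent neighbor counts {sorted(counts)} vs n={n_neighbors}"
            )
    df = pd.DataFrame(
        [_record_row(r, n_neighbors) for r in records],
        columns=results_columns(n_neighbors),
    )
    df["label"] = df["label"].astype(int) if len(df) else df["label"]
    df.to_csv(path, index=False, float_format="%.6f")


def read_results(path):
    return pd.read_csv(path)
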