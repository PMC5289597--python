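"""Minimal MRC2014 volume I/O (modes 0, 1, 2).

Only the subset of the CCP-EM MRC2014 format needed for grayscale
tomogram stacks is supported: 3D volumes stored in modes 0 (int8),
1 (int16) or 2 (float32), C-ordered with x fastest.  The extended
header is skipped on read and never written.
"""

from __future__ import annotations

import struct

import numpy as np

HEADER_BYTES = 1024

_MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
}
_DTYPE_MODES = {v: k for k, v in _MODE_DTYPES.items()}


class MrcFormatError(ValueError):
    """Raised when a file cannot be parsed as a supported MRC volume."""


def read_mrc(path):
    """Read an MRC volume.

    Returns
    -------
    data : ndarray, shape (nz, ny, nx)
    voxel_size : tuple of float
        (x, y, z) cell spacing in angstrom per voxel; zeros if absent.
    """
    with open(path, "rb") as fh:
        header = fh.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise MrcFormatError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        machst = header[212:214]
        # big-endian files flag 0x11 0x11 in MACHST; reject rather than guess
        if machst == b"\x11\x11":
            raise MrcFormatError(f"{path}: big-endian MRC not supported")
        if mode not in _MODE_DTYPES:
            raise MrcFormatError(f"{path}: unsupported MRC mode {mode}")
        if min(nx, ny, nz) < 1:
            raise MrcFormatError(f"{path}: non-positive MRC dimensions")
        mx, my, mz = struct.unpack("<3i", header[28:40])
        xlen, ylen, zlen = struct.unpack("<3f", header[40:52])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        if nsymbt < 0:
            raise MrcFormatError(f"{path}: negative extended header size")
        fh.seek(HEADER_BYTES + nsymbt)
        dtype = _MODE_DTYPES[mode]
        count = nx * ny * nz
        raw = fh.read(count * dtype.itemsize)
        if len(raw) < count * dtype.itemsize:
            raise MrcFormatError(f"{path}: truncated MRC data block")
        data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx)
    voxel = tuple(
        (length / grid) if grid > 0 and length > 0 else 0.0
        for length, grid in ((xlen, mx), (ylen, my), (zlen, mz))
    )
    return data.copy(), voxel


def write_mrc(path, data, voxel_size=(1.0, 1.0, 1.0)):
    """Write a 3D array as little-endian MRC2014.

    ``voxel_size`` is (x, y, z) spacing in angstrom per voxel.  float64
    input is narrowed to float32 (mode 2); int8/int16/float32 are kept.
    """
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("MRC writer expects a 3D array")
    if data.dtype not in _DTYPE_MODES:
        data = data.astype(np.float32)
    mode = _DTYPE_MODES[data.dtype]
    nz, ny, nx = data.shape
    vx, vy, vz = voxel_size

    header = bytearray(HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart..nzstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx my mz
    struct.pack_into("<3f", header, 40, nx * vx, ny * vy, nz * vz)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc mapr maps
    dmin, dmax = float(data.min()), float(data.max())
    struct.pack_into("<3f", header, 76, dmin, dmax, float(data.mean()))
    struct.pack_into("<i", header, 88, 1)  # ispg: volume
    header[208:212] = b"MAP "
    header[212:214] = b"\x44\x44"  # little-endian MACHST
    struct.pack_into("<f", header, 216, float(data.std()))

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data).tobytes())
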