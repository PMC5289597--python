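"""Synthetic tomogram-like phantoms with known vesicle ground truth.

A phantom emulates the imaging situation the pipeline is built for:
dark spherical membrane shells around lighter lumina, a granular
cytoplasmic field (dark grains on a brighter matrix), additive noise,
anisotropic z sampling, a polygonal cell boundary, and non-vesicular
confounders (membrane-bounded rods, oversized and undersized blobs).

Shells are rendered by 3x supersampled occupancy per voxel so that
sub-voxel membrane thickness survives rendering at 1 nm/px.  A fixed
seed yields bit-identical stacks and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon

from .io_formats import PolygonRoi, TomogramStack

__all__ = [
    "PhantomParams",
    "GroundTruthTable",
    "PhantomGenerationError",
    "generate_phantom",
    "generate_doublet",
]

GT_COLUMNS = [
    "id",
    "center_x_nm",
    "center_y_nm",
    "center_z_nm",
    "inner_diameter_nm",
    "outer_diameter_nm",
    "fused",
]


class PhantomGenerationError(RuntimeError):
    """Raised when object placement is infeasible after bounded retries."""


@dataclass
class PhantomParams:
    shape_vx: tuple = (60, 300, 300)  # (z, y, x)
    voxel_depth_z: float = 1.6
    n_vesicles: int = 40
    inner_diam_mean_nm: float = 40.0
    inner_diam_sd_nm: float = 5.0
    shell_thickness_nm: float = 4.45
    min_separation_nm: float = 30.0
    lumen_level: float = 200.0
    shell_level: float = 60.0
    cytoplasm_level: float = 205.0
    noise_sd: float = 8.0
    texture_grain_nm: float = 6.5
    texture_depth: float = 160.0
    texture_coverage: float = 0.75
    n_confounders: int = 0
    cell_polygon_margin_px: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.shell_level < self.lumen_level <= self.cytoplasm_level:
            raise ValueError("need shell_level < lumen_level <= cytoplasm_level")
        if self.n_vesicles < 0:
            raise ValueError("n_vesicles must be >= 0")
        if self.min_separation_nm <= 0:
            raise ValueError("min_separation_nm must be positive")
        if self.inner_diam_mean_nm <= 0 or self.shell_thickness_nm <= 0:
            raise ValueError("diameter law and shell thickness must be positive")


@dataclass
class GroundTruthTable:
    """Per-vesicle ground truth plus (separately) injected confounders."""

    table: pd.DataFrame
    confounders: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["id", "kind", "center_x_nm", "center_y_nm", "center_z_nm",
                     "size_nm", "radial_nm", "axis_x", "axis_y", "axis_z"]
        )
    )

    def __len__(self):
        return len(self.table)

    def centers(self):
        return self.table[
            ["center_x_nm", "center_y_nm", "center_z_nm"]
        ].to_numpy(dtype=float)

    def confounder_clearance(self, points):
        """Distance (nm) from each point to the nearest confounder
        surface: negative or near zero means the point lies inside or on
        a confounder (rods measured against their axis segment)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(points), np.inf)
        for _, row in self.confounders.iterrows():
            center = np.array([row.center_x_nm, row.center_y_nm,
                               row.center_z_nm])
            if row.kind == "rod" and np.isfinite(row.axis_x):
                axis = np.array([row.axis_x, row.axis_y, row.axis_z])
                half = axis * (row.size_nm / 2.0 - (row.radial_nm - 4.45))
                rel = points - (center - half)
                seg = 2.0 * half
                denom = float(seg @ seg)
                t = np.clip((rel @ seg) / max(denom, 1e-12), 0.0, 1.0)
                d = np.linalg.norm(rel - t[:, None] * seg[None, :], axis=1)
                d -= row.radial_nm
            else:
                d = np.linalg.norm(points - center, axis=1) - row.size_nm / 2.0
            out = np.minimum(out, d)
        return out

    def write(self, path):
        self.table.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read(cls, path):
        df = pd.read_csv(path)
        if "fused" not in df.columns:
            df["fused"] = False
        return cls(table=df)


# ---------------------------------------------------------------------------
# geometry helpers

_SUB = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])


def _cell_polygon(shape_vx, margin_px):
    """Chamfered-rectangle cell boundary inset by ``margin_px``."""
    _, ny, nx = shape_vx
    lo_x, hi_x = float(margin_px), float(nx - 1 - margin_px)
    lo_y, hi_y = float(margin_px), float(ny - 1 - margin_px)
    if hi_x - lo_x <= 4 or hi_y - lo_y <= 4:
        raise ValueError("margin leaves no cell area")
    c = min(25.0, (hi_x - lo_x) / 4.0, (hi_y - lo_y) / 4.0)  # corner chamfer
    return np.array([
        (lo_x + c, lo_y), (hi_x - c, lo_y), (hi_x, lo_y + c),
        (hi_x, hi_y - c), (hi_x - c, hi_y), (lo_x + c, hi_y),
        (lo_x, hi_y - c), (lo_x, lo_y + c),
    ])


def _sphere_occupancy(shape_vx, dz, center, r_inner, r_outer):
    """Supersampled lumen/shell occupancy fractions in the sphere's bbox.

    Returns (bbox slices, lumen_frac, shell_frac), fractions in [0, 1].
    """
    nz, ny, nx = shape_vx
    cx, cy, cz = center
    r = r_outer + 1.5
    z0, z1 = int((cz - r) / dz) - 1, int(np.ceil((cz + r) / dz)) + 2
    y0, y1 = int(cy - r) - 1, int(np.ceil(cy + r)) + 2
    x0, x1 = int(cx - r) - 1, int(np.ceil(cx + r)) + 2
    z0, y0, x0 = max(z0, 0), max(y0, 0), max(x0, 0)
    z1, y1, x1 = min(z1, nz), min(y1, ny), min(x1, nx)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return None, None, None
    zz = np.arange(z0, z1) * dz - cz
    yy = np.arange(y0, y1) * 1.0 - cy
    xx = np.arange(x0, x1) * 1.0 - cx
    lum = np.zeros((z1 - z0, y1 - y0, x1 - x0))
    shl = np.zeros_like(lum)
    for oz in _SUB * dz:
        for oy in _SUB:
            for ox in _SUB:
                d2 = (
                    (zz + oz)[:, None, None] ** 2
                    + (yy + oy)[None, :, None] ** 2
                    + (xx + ox)[None, None, :] ** 2
                )
                lum += d2 < r_inner**2
                shl += (d2 >= r_inner**2) & (d2 <= r_outer**2)
    bbox = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
    return bbox, lum / 27.0, shl / 27.0


def _capsule_occupancy(shape_vx, dz, p0, p1, r_inner, r_outer):
    """Occupancy fractions for a capsule (cylinder with spherical caps)."""
    nz, ny, nx = shape_vx
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    r = r_outer + 1.5
    lo = np.minimum(p0, p1) - r
    hi = np.maximum(p0, p1) + r
    x0, y0, z0 = int(lo[0]) - 1, int(lo[1]) - 1, int(lo[2] / dz) - 1
    x1, y1, z1 = int(np.ceil(hi[0])) + 2, int(np.ceil(hi[1])) + 2, int(
        np.ceil(hi[2] / dz)
    ) + 2
    z0, y0, x0 = max(z0, 0), max(y0, 0), max(x0, 0)
    z1, y1, x1 = min(z1, nz), min(y1, ny), min(x1, nx)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return None, None, None
    axis = p1 - p0
    len2 = float(axis @ axis)
    lum = np.zeros((z1 - z0, y1 - y0, x1 - x0))
    shl = np.zeros_like(lum)
    zz = np.arange(z0, z1) * dz
    yy = np.arange(y0, y1) * 1.0
    xx = np.arange(x0, x1) * 1.0
    for oz in _SUB * dz:
        for oy in _SUB:
            for ox in _SUB:
                pz = (zz + oz)[:, None, None] - p0[2]
                py = (yy + oy)[None, :, None] - p0[1]
                px = (xx + ox)[None, None, :] - p0[0]
                t = (px * axis[0] + py * axis[1] + pz * axis[2]) / len2
                np.clip(t, 0.0, 1.0, out=t)
                d2 = (
                    (px - t * axis[0]) ** 2
                    + (py - t * axis[1]) ** 2
                    + (pz - t * axis[2]) ** 2
                )
                lum += d2 < r_inner**2
                shl += (d2 >= r_inner**2) & (d2 <= r_outer**2)
    bbox = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
    return bbox, lum / 27.0, shl / 27.0


def _background_field(params, rng):
    """Cytoplasmic matrix with dark Gaussian-correlated granules.

    The granular texture is subtractive (grains are electron-dense),
    which both reproduces the look of cytoplasm and places the slice
    mean between shell and lumen levels, as in real stacks where about
    half of each slice is occupied by dense material.
    """
    nz, ny, nx = params.shape_vx
    white = rng.standard_normal((nz, ny, nx))
    sigma_xy = max(params.texture_grain_nm / 2.0, 0.5)
    sigma_z = max(sigma_xy / params.voxel_depth_z, 0.3)
    t = ndi.gaussian_filter(white, (sigma_z, sigma_xy, sigma_xy))
    std = t.std()
    if std > 0:
        t /= std
    # occupancy ramps from 0 to 1 across a soft threshold placed at the
    # requested coverage quantile of the correlated field
    from scipy.special import ndtri

    thr = ndtri(params.texture_coverage)
    grain = np.clip((thr - t) / 0.5 + 0.5, 0.0, 1.0)
    return params.cytoplasm_level - params.texture_depth * grain


def _render(params, spheres, capsules, rng):
    """Composite occupancies onto the textured background; shell wins
    over lumen where membranes cross other objects."""
    field = _background_field(params, rng)
    lum_occ = np.zeros(params.shape_vx)
    shl_occ = np.zeros(params.shape_vx)
    for center, r_in, r_out in spheres:
        bbox, lum, shl = _sphere_occupancy(
            params.shape_vx, params.voxel_depth_z, center, r_in, r_out
        )
        if bbox is None:
            continue
        lum_occ[bbox] += lum
        shl_occ[bbox] += shl
    for p0, p1, r_in, r_out in capsules:
        bbox, lum, shl = _capsule_occupancy(
            params.shape_vx, params.voxel_depth_z, p0, p1, r_in, r_out
        )
        if bbox is None:
            continue
        lum_occ[bbox] += lum
        shl_occ[bbox] += shl
    # where two lumina would interpenetrate, fused vesicles share a
    # membrane wall: the overlap volume becomes shell material
    overlap = np.clip(lum_occ - 1.0, 0.0, 1.0)
    shl_occ = np.clip(shl_occ + overlap, 0.0, 1.0)
    lum_occ = np.clip(lum_occ - 2.0 * overlap, 0.0, 1.0 - shl_occ)
    out = (
        field * (1.0 - shl_occ - lum_occ)
        + params.shell_level * shl_occ
        + params.lumen_level * lum_occ
    )
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape)
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# placement

def _sample_centers(params, specs, rng, max_tries_per_object=8000,
                    max_restarts=25):
    """Dart-throwing placement inside the cell polygon.

    ``specs`` is a list of (clearance_r, z_margin, xy_buffer, half_vec)
    per object, ``half_vec`` being None for spheres or the capsule's
    axis half-vector.  Clearance between two objects is
    max(min_separation_nm, clearance_i + clearance_j + 3 nm) measured
    between their core segments (a sphere is a zero-length segment):
    lumina never overlap and always keep at least a membrane's worth of
    material between them, while shells may interpenetrate as in dense
    vesicle pools.  Objects are placed largest-first; the whole
    configuration is restarted with fresh darts when placement jams.
    Requests near the jamming limit of random sequential placement fall
    back, after a few restarts, to proposals drawn from a jittered
    two-layer hexagonal lattice (still seeded, still clearance-checked).
    """
    nz, ny, nx = params.shape_vx
    dz = params.voxel_depth_z
    poly = Polygon(_cell_polygon(params.shape_vx, params.cell_polygon_margin_px))
    order = np.argsort([s[0] for s in specs])[::-1]

    def _lattice_sites():
        """Two square-lattice layers, the upper staggered diagonally so
        cross-layer neighbors gain in-plane offset on top of the z gap."""
        spacing = max(params.min_separation_nm,
                      params.inner_diam_mean_nm + 6.0)
        depth = (nz - 1) * dz
        sites = []
        minx, miny, maxx, maxy = poly.bounds
        for layer, zfrac in enumerate((0.26, 0.74)):
            shift = layer * spacing / 2.0
            for y in np.arange(miny + shift, maxy, spacing):
                for x in np.arange(minx + shift, maxx, spacing):
                    sites.append((
                        x + rng.uniform(-3, 3),
                        y + rng.uniform(-3, 3),
                        depth * zfrac + rng.uniform(-5, 5),
                    ))
        return [sites[i] for i in rng.permutation(len(sites))]

    regions = {}
    for _, _, xy_buffer, _ in specs:
        if xy_buffer not in regions:
            region = poly.buffer(-(xy_buffer + 1.0))
            if region.is_empty:
                raise PhantomGenerationError(
                    f"cell region too small for xy extent {xy_buffer:.1f}"
                )
            regions[xy_buffer] = region

    ts = np.linspace(-1.0, 1.0, 9)

    def _sample_pts(center, half_vec):
        center = np.asarray(center)
        if half_vec is None:
            return center[None, :]
        return center[None, :] + ts[:, None] * np.asarray(half_vec)[None, :]

    for restart in range(max_restarts):
        lattice = _lattice_sites() if restart >= 4 else None
        centers = [None] * len(specs)
        placed = []  # (sample points, core radius)
        jammed = False
        for idx in order:
            clearance_r, z_margin, xy_buffer, half_vec = specs[idx]
            core_r = (
                clearance_r if half_vec is None
                else clearance_r - np.linalg.norm(half_vec)
            )
            region = regions[xy_buffer]
            minx, miny, maxx, maxy = region.bounds
            z_lo = z_margin + dz
            z_hi = (nz - 1) * dz - z_margin - dz
            if z_hi <= z_lo:
                raise PhantomGenerationError("stack too thin for object extent")
            use_lattice = lattice is not None and half_vec is None
            n_tries = len(lattice) if use_lattice else max_tries_per_object
            for trial in range(n_tries):
                if use_lattice:
                    x, y, z = lattice[trial]
                    z = float(np.clip(z, z_lo, z_hi))
                else:
                    x = rng.uniform(minx, maxx)
                    y = rng.uniform(miny, maxy)
                    z = rng.uniform(z_lo, z_hi)
                if not region.contains(Point(x, y)):
                    continue
                pts = _sample_pts((x, y, z), half_vec)
                ok = True
                for other_pts, other_r in placed:
                    gap = max(params.min_separation_nm, core_r + other_r + 3.0)
                    d2 = (
                        (pts[:, None, :] - other_pts[None, :, :]) ** 2
                    ).sum(axis=2)
                    if d2.min() < gap**2:
                        ok = False
                        break
                if ok:
                    centers[idx] = (x, y, z)
                    placed.append((pts, core_r))
                    if use_lattice:
                        lattice.pop(trial)
                    break
            else:
                jammed = True
                break
        if not jammed:
            return centers
    raise PhantomGenerationError(
        f"could not place {len(specs)} objects after {max_restarts} restarts"
    )


def _check_packing(params, inner_radii):
    """Feasibility guard: expected total lumen volume <= 30% of the cell."""
    poly = Polygon(_cell_polygon(params.shape_vx, params.cell_polygon_margin_px))
    nz = params.shape_vx[0]
    cell_volume = poly.area * nz * params.voxel_depth_z
    total = sum(4.0 / 3.0 * np.pi * r**3 for r in inner_radii)
    if total > 0.3 * cell_volume:
        raise PhantomGenerationError(
            f"requested vesicle volume {total:.0f} exceeds 30% of the "
            f"cell volume {cell_volume:.0f}"
        )


def _boundary_rois(params):
    verts = _cell_polygon(params.shape_vx, params.cell_polygon_margin_px)
    nz = params.shape_vx[0]
    return PolygonRoi(0, verts.copy()), PolygonRoi(nz - 1, verts.copy())


def generate_phantom(params):
    """Generate a phantom stack, its ground-truth table and the two
    boundary-polygon ROIs (first and last slice).

    Confounders are injected in a rod / small-blob / large-blob rotation:
    membrane-bounded capsules with axis ratio >= 3, blobs below the
    typical volume minimum, and oversized blobs.
    """
    rng = np.random.default_rng(params.seed)
    t = params.shell_thickness_nm

    inner_d = np.empty(0)
    if params.n_vesicles:
        inner_d = rng.normal(
            params.inner_diam_mean_nm,
            params.inner_diam_sd_nm,
            size=params.n_vesicles,
        )
        lo = params.inner_diam_mean_nm - 3.0 * params.inner_diam_sd_nm
        hi = params.inner_diam_mean_nm + 3.0 * params.inner_diam_sd_nm
        inner_d = np.clip(inner_d, max(lo, 4.0), hi)

    kinds = ["rod", "blob_small", "blob_large"]
    conf_kinds = [kinds[i % 3] for i in range(params.n_confounders)]

    dz = params.voxel_depth_z
    nz = params.shape_vx[0]
    depth = (nz - 1) * dz

    # placement specs: (clearance radius, z margin, xy buffer, half_vec)
    specs = [(d / 2.0, d / 2.0, d / 2.0, None) for d in inner_d]
    conf_geom = []
    for kind in conf_kinds:
        if kind == "rod":
            r_in = rng.uniform(5.0, 6.5)
            length = rng.uniform(3.2, 3.8) * 2.0 * r_in  # axis ratio >= 3
            axis = rng.standard_normal(3)
            axis[2] *= 0.2  # tubular structures lie mostly in-plane
            axis /= np.linalg.norm(axis)
            max_span = max(depth / 2.0 - r_in - t - 2.0 * dz, 1.0)
            if abs(axis[2]) * length / 2.0 > max_span:
                axis[2] = np.sign(axis[2]) * max_span / (length / 2.0)
                nrm = np.linalg.norm(axis[:2])
                axis[:2] *= np.sqrt(max(1 - axis[2] ** 2, 1e-9)) / max(nrm, 1e-9)
            conf_geom.append((kind, r_in, length, axis))
            half = axis * (length / 2.0 - r_in)
            z_margin = abs(axis[2]) * length / 2.0 + r_in + t
            specs.append(
                (r_in + np.linalg.norm(half), z_margin, length / 2.0, half)
            )
        elif kind == "blob_small":
            r_in = rng.uniform(4.0, 7.0)  # interior volume well below minima
            conf_geom.append((kind, r_in, 0.0, None))
            specs.append((r_in, r_in, r_in, None))
        else:
            # oversized solid dark blob (dense organelle); may poke out in z
            r_in = rng.uniform(22.0, 28.0)
            conf_geom.append((kind, r_in, 0.0, None))
            specs.append((r_in, min(r_in, depth * 0.3), r_in, None))

    _check_packing(params, [d / 2.0 for d in inner_d])
    centers = _sample_centers(params, specs, rng)

    spheres = []
    rows = []
    for i, d in enumerate(inner_d):
        r_in = d / 2.0
        c = centers[i]
        spheres.append((c, r_in, r_in + t))
        rows.append(
            {
                "id": i + 1,
                "center_x_nm": c[0],
                "center_y_nm": c[1],
                "center_z_nm": c[2],
                "inner_diameter_nm": d,
                "outer_diameter_nm": d + 2.0 * t,
                "fused": False,
            }
        )

    capsules = []
    conf_rows = []
    for j, (kind, r_in, length, axis) in enumerate(conf_geom):
        c = np.asarray(centers[params.n_vesicles + j])
        if kind == "rod":
            half = axis * (length / 2.0 - r_in)
            capsules.append((c - half, c + half, r_in, r_in + t))
            size = length
        elif kind == "blob_small":
            spheres.append((tuple(c), r_in, r_in + t))
            size = 2.0 * r_in
        else:
            # solid dark ball: inner radius 0 renders shell material only
            spheres.append((tuple(c), 0.0, r_in + t))
            size = 2.0 * r_in
        ax = axis if kind == "rod" else (np.nan, np.nan, np.nan)
        conf_rows.append(
            {
                "id": j + 1,
                "kind": kind,
                "center_x_nm": c[0],
                "center_y_nm": c[1],
                "center_z_nm": c[2],
                "size_nm": size,
                "radial_nm": r_in + t,
                "axis_x": ax[0],
                "axis_y": ax[1],
                "axis_z": ax[2],
            }
        )

    voxels = _render(params, spheres, capsules, rng)
    stack = TomogramStack(
        voxels=voxels,
        px_size_xy=1.0,
        voxel_depth_z=params.voxel_depth_z,
        source_path=f"phantom(seed={params.seed})",
    )
    gt = GroundTruthTable(
        table=pd.DataFrame(rows, columns=GT_COLUMNS),
        confounders=pd.DataFrame(
            conf_rows,
            columns=["id", "kind", "center_x_nm", "center_y_nm",
                     "center_z_nm", "size_nm", "radial_nm",
                     "axis_x", "axis_y", "axis_z"],
        ),
    )
    roi_first, roi_last = _boundary_rois(params)
    return stack, gt, roi_first, roi_last


def generate_doublet(params, separation_fraction):
    """Two equal vesicles at a stated center separation (as a fraction of
    the mean inner diameter), randomly oriented from the seed."""
    if not 0.5 <= separation_fraction <= 1.5:
        raise ValueError("separation_fraction must be in [0.5, 1.5]")
    rng = np.random.default_rng(params.seed)
    t = params.shell_thickness_nm
    d = params.inner_diam_mean_nm
    r_in = d / 2.0
    sep = separation_fraction * d
    nz, ny, nx = params.shape_vx
    dz = params.voxel_depth_z
    center = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) * dz / 2.0])
    # random orientation, z-component limited so both spheres stay inside
    axis = rng.standard_normal(3)
    max_dz = max((nz - 1) * dz / 2.0 - r_in - t - 2 * dz, 0.0)
    axis /= np.linalg.norm(axis)
    if abs(axis[2]) * sep / 2.0 > max_dz:
        axis[2] = np.sign(axis[2]) * max_dz / (sep / 2.0)
        nrm = np.linalg.norm(axis[:2])
        scale = np.sqrt(max(1.0 - axis[2] ** 2, 1e-9)) / max(nrm, 1e-9)
        axis[:2] *= scale
    c1 = center - axis * sep / 2.0
    c2 = center + axis * sep / 2.0
    spheres = [(tuple(c1), r_in, r_in + t), (tuple(c2), r_in, r_in + t)]
    voxels = _render(params, spheres, [], rng)
    stack = TomogramStack(
        voxels=voxels,
        px_size_xy=1.0,
        voxel_depth_z=dz,
        source_path=f"doublet(seed={params.seed},f={separation_fraction})",
    )
    rows = []
    for i, c in enumerate((c1, c2)):
        rows.append(
            {
                "id": i + 1,
                "center_x_nm": c[0],
                "center_y_nm": c[1],
                "center_z_nm": c[2],
                "inner_diameter_nm": d,
                "outer_diameter_nm": d + 2.0 * t,
                "fused": separation_fraction < 1.0,
            }
        )
    gt = GroundTruthTable(table=pd.DataFrame(rows, columns=GT_COLUMNS))
    return stack, gt
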