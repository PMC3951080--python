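"""Voxelized world construction: CT import, contour rasterization, enclosures.

Coordinate convention: world coordinates in cm, axes ordered (x, y, z) with z
the crown–rump (long) axis.  Voxel indices are 0-based; voxel i spans
[origin + i*spacing, origin + (i+1)*spacing) — half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .materials import (
    BUILTIN_MATERIALS,
    HUConversionTable,
    Material,
    get_material,
)

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "CTSlice",
    "rasterize_contour",
    "load_ct",
    "add_enclosure",
]


@dataclass
class VoxelGrid:
    """Rectilinear voxel world: per-voxel material index and density.

    ``materials`` maps material_index -> Material; ``material_index`` and
    ``density`` are (nx, ny, nz) arrays.
    """

    origin: np.ndarray  # (3,) cm, corner of voxel (0,0,0)
    spacing: np.ndarray  # (3,) cm
    material_index: np.ndarray  # (nx,ny,nz) int16
    density: np.ndarray  # (nx,ny,nz) float32/64, g/cm^3
    materials: list = field(default_factory=list)  # index -> Material

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0 on every axis")
        if self.material_index.shape != self.density.shape:
            raise ValueError("material_index and density shapes differ")
        if self.material_index.size and self.material_index.max() >= len(self.materials):
            raise ValueError("material_index does not resolve in the material list")
        if np.any(self.density <= 0):
            raise ValueError("density must be > 0 everywhere")

    @property
    def dims(self) -> tuple:
        return self.material_index.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> np.ndarray:
        """(2,3) world-coordinate bounding box [min; max]."""
        mx = self.origin + self.spacing * np.asarray(self.dims)
        return np.array([self.origin, mx])

    @property
    def center(self) -> np.ndarray:
        return self.extent.mean(axis=0)

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def voxel_mass(self) -> np.ndarray:
        """Per-voxel mass in g."""
        return self.density * self.voxel_volume

    def material_names(self) -> list:
        return [m.name for m in self.materials]


@dataclass
class StructureMask:
    """Named boolean mask aligned to a VoxelGrid."""

    name: str
    mask: np.ndarray  # (nx,ny,nz) bool

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_cm3(self, grid: VoxelGrid) -> float:
        return self.volume_voxels * grid.voxel_volume


@dataclass
class CTSlice:
    """One axial CT slice: HU array indexed [ix, iy], plus placement.

    This is the in-memory representation used both by the synthetic fixtures
    and by the (optional) DICOM reader.
    """

    hu: np.ndarray  # (nx, ny)
    z_position: float  # cm, lower edge of the slice
    pixel_spacing: tuple  # (dx, dy) cm
    origin_xy: tuple = (0.0, 0.0)  # cm, corner of pixel (0,0)
    thickness: float = 0.0  # cm; 0 -> infer from slice spacing


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _polygon_self_intersects(poly: np.ndarray) -> bool:
    n = len(poly)
    for i in range(n):
        a1, a2 = poly[i], poly[(i + 1) % n]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # shares the closing vertex
            if _segments_intersect(a1, a2, poly[j], poly[(j + 1) % n]):
                return True
    return False


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even–odd (crossing-number) point-in-polygon test, vectorized over points."""
    inside = np.zeros(px.shape, dtype=bool)
    x, y = poly[:, 0], poly[:, 1]
    n = len(poly)
    for i in range(n):
        j = (i - 1) % n
        cond = (y[i] > py) != (y[j] > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = (x[j] - x[i]) * (py - y[i]) / (y[j] - y[i]) + x[i]
        inside ^= cond & (px < xint)
    return inside


def rasterize_contour(polygons_by_slice: dict, grid: VoxelGrid, name: str = "mask") -> StructureMask:
    """Rasterize per-slice closed polygons into a voxel mask.

    ``polygons_by_slice`` maps slice index (along z) -> list of (N,2) arrays of
    (x, y) world-coordinate vertices.  A voxel is inside iff its center is
    inside a polygon under the even–odd rule.  Self-intersecting polygons are
    rasterized anyway with a warning.
    """
    nx, ny, nz = grid.dims
    mask = np.zeros(grid.dims, dtype=bool)
    xc = grid.axis_centers(0)
    yc = grid.axis_centers(1)
    px, py = np.meshgrid(xc, yc, indexing="ij")
    for iz, polys in polygons_by_slice.items():
        if not 0 <= iz < nz:
            continue
        for poly in polys:
            poly = np.asarray(poly, dtype=float)
            if len(poly) < 3:
                continue
            if _polygon_self_intersects(poly):
                warnings.warn(f"self-intersecting polygon on slice {iz}; "
                              "even-odd result returned")
            mask[:, :, iz] ^= _points_in_polygon(px, py, poly)
    return StructureMask(name=name, mask=mask)


def load_ct(slices: list, body_contours: dict, table: HUConversionTable):
    """Build a voxelized world from CT slices and a BODY contour.

    Voxels inside BODY are mapped through the HU conversion table; voxels
    outside BODY are set to air.  The grid is cropped to the BODY bounding
    box.  Returns (VoxelGrid, StructureMask('BODY')).

    ``slices`` is a list of :class:`CTSlice` (uniform shape/spacing, ascending
    z, uniform z spacing); ``body_contours`` maps slice index -> polygon list
    as for :func:`rasterize_contour`.
    """
    if not slices:
        raise ValueError("no CT slices given")
    shape0 = slices[0].hu.shape
    spacing0 = slices[0].pixel_spacing
    origin0 = slices[0].origin_xy
    for s in slices:
        if s.hu.shape != shape0 or s.pixel_spacing != spacing0 or s.origin_xy != origin0:
            raise ValueError("CT slices are not uniform in shape/spacing/origin")
    zpos = np.array([s.z_position for s in slices], dtype=float)
    if len(slices) > 1:
        dz_all = np.diff(zpos)
        dz = dz_all[0]
        if dz <= 0 or not np.allclose(dz_all, dz, rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform or non-ascending slice spacing")
    else:
        dz = slices[0].thickness or min(spacing0)

    nx, ny = shape0
    nz = len(slices)
    hu = np.stack([s.hu for s in slices], axis=-1).astype(float)

    # full-extent grid, everything air for now
    air_idx = len(table.entries)  # appended after the table materials
    materials = [get_material(n) for n in table.materials] + [get_material("air")]
    mat_index = np.full((nx, ny, nz), air_idx, dtype=np.int16)
    density = np.full((nx, ny, nz), BUILTIN_MATERIALS["air"].density, dtype=np.float64)
    grid = VoxelGrid(origin=np.array([origin0[0], origin0[1], zpos[0]]),
                     spacing=np.array([spacing0[0], spacing0[1], dz]),
                     material_index=mat_index, density=density, materials=materials)

    # BODY contours must be closed rings (first vertex repeats as last);
    # the duplicated closing vertex is stripped before rasterization.
    ring_contours = {}
    for iz, polys in body_contours.items():
        rings = []
        for poly in polys:
            p = np.asarray(poly, dtype=float)
            if len(p) < 4 or not np.allclose(p[0], p[-1]):
                raise ValueError(f"unclosed BODY contour on slice {iz}")
            rings.append(p[:-1])
        ring_contours[iz] = rings
    body = rasterize_contour(ring_contours, grid, name="BODY")
    if not body.mask.any():
        raise ValueError("BODY contour rasterized to an empty mask")

    # HU lookup inside BODY (vectorized over the table bins)
    inside = body.mask
    hu_in = hu[inside]
    lo = table.entries[0][0]
    hi = table.entries[-1][1]
    hu_clamped = np.clip(hu_in, lo, hi)
    edges = np.array([e[1] for e in table.entries[:-1]])
    bin_idx = np.searchsorted(edges, hu_clamped, side="left")
    intercepts = np.array([e[3][0] for e in table.entries])
    slopes = np.array([e[3][1] for e in table.entries])
    dens_in = np.maximum(intercepts[bin_idx] + slopes[bin_idx] * hu_clamped, 1e-6)
    mat_index[inside] = bin_idx.astype(np.int16)
    density[inside] = dens_in

    # crop to the BODY bounding box
    idx = np.nonzero(inside)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    cropped = VoxelGrid(
        origin=grid.origin + np.array([s.start for s in sl]) * grid.spacing,
        spacing=grid.spacing.copy(),
        material_index=mat_index[sl].copy(),
        density=density[sl].copy(),
        materials=materials,
    )
    return cropped, StructureMask(name="BODY", mask=inside[sl].copy())


def add_enclosure(grid: VoxelGrid, wall_thickness: float, air_gap: float,
                  axes: tuple = (0, 1)) -> VoxelGrid:
    """Pad the grid with an air gap then a PMMA wall on the lateral faces.

    ``axes`` selects which axes get padded (default x and y — all faces
    perpendicular to the crown–rump axis).  Layer counts are rounded to the
    nearest voxel.  The original voxel payload is unchanged.
    """
    if wall_thickness < 0 or air_gap < 0:
        raise ValueError("wall_thickness and air_gap must be >= 0")
    air = get_material("air")
    pmma = get_material("pmma")
    materials = list(grid.materials)

    def _index_of(mat: Material) -> int:
        for i, m in enumerate(materials):
            if m.name == mat.name:
                return i
        materials.append(mat)
        return len(materials) - 1

    air_idx = _index_of(air)
    pmma_idx = _index_of(pmma)

    n_gap = np.zeros(3, dtype=int)
    n_wall = np.zeros(3, dtype=int)
    for ax in axes:
        n_gap[ax] = int(round(air_gap / grid.spacing[ax]))
        n_wall[ax] = int(round(wall_thickness / grid.spacing[ax]))
    pad = n_gap + n_wall
    dims = np.asarray(grid.dims) + 2 * pad
    mat = np.full(tuple(dims), air_idx, dtype=np.int16)
    den = np.full(tuple(dims), air.density, dtype=np.float64)
    # the wall is a closed shell (in the padded axes) around the gap+payload box
    inside_gap_box = np.ones(tuple(dims), dtype=bool)
    for ax in axes:
        idx = np.arange(dims[ax])
        in_ax = (idx >= n_wall[ax]) & (idx < dims[ax] - n_wall[ax])
        shape = [1, 1, 1]
        shape[ax] = dims[ax]
        inside_gap_box &= in_ax.reshape(shape)
    mat[~inside_gap_box] = pmma_idx
    den[~inside_gap_box] = pmma.density
    payload = tuple(slice(p, p + n) for p, n in zip(pad, grid.dims))
    mat[payload] = grid.material_index
    den[payload] = grid.density
    origin = grid.origin - pad * grid.spacing
    return VoxelGrid(origin=origin, spacing=grid.spacing.copy(),
                     material_index=mat, density=den, materials=materials)
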