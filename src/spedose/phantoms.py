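"""Synthetic geometry generators: slabs, air-gap rigs, and a digital minipig.

All generators are deterministic functions of their arguments (no RNG).  The
digital animal is an idealized stand-in for real CT datasets: a prolate
ellipsoidal soft-tissue body whose every proportion is a fixed multiple of
the crown-rump length, so two animals of different size differ only by a
similarity transform and their organ volumes scale exactly with length cubed
(up to voxelization).
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import StructureMask, VoxelGrid
from .materials import get_material

__all__ = ["make_slab_phantom", "make_airgap_rig", "make_digital_animal",
           "ANIMAL_PROPORTIONS"]


def make_slab_phantom(material: str, size, voxel) -> VoxelGrid:
    """Homogeneous box of a named material at its reference density.

    ``size`` is (sx, sy, sz) cm (a scalar means a cube); ``voxel`` the
    spacing in cm (scalar isotropic or per-axis).  The box is centered on the
    origin.  Sizes must be voxel multiples within rounding.
    """
    mat = get_material(material)
    size = np.broadcast_to(np.asarray(size, dtype=float), 3).copy()
    voxel = np.broadcast_to(np.asarray(voxel, dtype=float), 3).copy()
    dims = np.round(size / voxel).astype(int)
    if np.any(np.abs(dims * voxel - size) > 1e-6 * voxel):
        raise ValueError("size must be a multiple of the voxel spacing")
    if np.any(dims < 1):
        raise ValueError("phantom must be at least one voxel across")
    mat_index = np.zeros(tuple(dims), dtype=np.int16)
    density = np.full(tuple(dims), mat.density, dtype=np.float64)
    return VoxelGrid(origin=-size / 2.0, spacing=voxel,
                     material_index=mat_index, density=density,
                     materials=[mat])


def make_airgap_rig(gap: float, wall: float = 0.5,
                    phantom: VoxelGrid = None) -> VoxelGrid:
    """PMMA wall + air gap stacked upstream (low-x side) of a phantom.

    The wall's upstream face is held fixed at x = 0 for every gap, so the
    phantom recedes as the gap grows (the source-to-wall distance is what the
    experiment holds constant).  Layer counts use the phantom's x spacing;
    the phantom voxel payload is unchanged.
    """
    if gap < 0 or wall < 0:
        raise ValueError("gap and wall must be >= 0")
    if phantom is None:
        phantom = make_slab_phantom("solid_water", 20.0, 0.1)
    air = get_material("air")
    pmma = get_material("pmma")
    materials = list(phantom.materials)
    names = [m.name for m in materials]

    def _idx(m):
        if m.name in names:
            return names.index(m.name)
        materials.append(m)
        names.append(m.name)
        return len(materials) - 1

    air_idx, pmma_idx = _idx(air), _idx(pmma)
    dx = phantom.spacing[0]
    n_wall = int(round(wall / dx))
    n_gap = int(round(gap / dx))
    nx, ny, nz = phantom.dims
    mat = np.empty((n_wall + n_gap + nx, ny, nz), dtype=np.int16)
    den = np.empty_like(mat, dtype=np.float64)
    mat[:n_wall] = pmma_idx
    den[:n_wall] = pmma.density
    mat[n_wall:n_wall + n_gap] = air_idx
    den[n_wall:n_wall + n_gap] = air.density
    mat[n_wall + n_gap:] = phantom.material_index
    den[n_wall + n_gap:] = phantom.density
    origin = phantom.origin.copy()
    origin[0] = 0.0  # wall upstream face pinned to x = 0
    return VoxelGrid(origin=origin, spacing=phantom.spacing.copy(),
                     material_index=mat, density=den, materials=materials)


# every length below is a fixed fraction of the crown-rump length L
# (reference case L = 54 cm); the digital animal is similarity-scaled.
ANIMAL_PROPORTIONS = {
    "girth_fraction": 0.55,       # transverse body diameter / L
    "skin_thickness": 0.2 / 54.0,  # 2 mm at the 54 cm reference
    "eye_radius": 0.75 / 54.0,     # 1.5 cm diameter at the reference
    "eye_center": (0.15, 0.25, 0.88),   # (x/a, y/b, z/c), mirrored in x
    "lung_center": (0.35, 0.0, 0.25),
    "lung_semiaxes": (0.32, 0.45, 0.22),  # fractions of (a, b, c)
    "spine_radius": 0.05,          # fraction of a
    "spine_y": 0.55,               # fraction of b (dorsal = +y)
    "spine_halflength": 0.70,      # fraction of c
    "limb_x": 0.45, "limb_z": 0.50,  # rod anchor fractions of (a, c)
    "limb_y": (-0.55, -0.10),      # rod extent, fractions of b (ventral)
    "limb_radius": 0.04,           # fraction of a
}


def make_digital_animal(crown_rump: float, voxel: float = 0.2):
    """Parameterized minipig-like body with skin, lungs, BFO and eye masks.

    Returns ``(grid, masks)`` where ``masks`` maps name -> StructureMask for
    BODY, skin, lungs, BFO and eyes.  Soft tissue body, 0.3 g/cm^3 lungs,
    bone-density skeleton rods (the BFO mask), soft-tissue eyes.  Organs are
    pairwise disjoint and all lie inside BODY.
    """
    if crown_rump <= 0:
        raise ValueError("crown_rump must be > 0")
    P = ANIMAL_PROPORTIONS
    L = float(crown_rump)
    c = L / 2.0
    a = b = P["girth_fraction"] * L / 2.0
    t_skin = P["skin_thickness"] * L
    if t_skin < 2 * voxel:
        warnings.warn("voxel too coarse to resolve the skin shell "
                      f"({t_skin:.3f} cm across {voxel:.3f} cm voxels)")

    margin = 2 * voxel
    half = np.array([a + margin, b + margin, c + margin])
    dims = np.ceil(2 * half / voxel).astype(int)
    origin = -dims * voxel / 2.0
    spacing = np.full(3, float(voxel))

    xs = (origin[0] + (np.arange(dims[0]) + 0.5) * voxel).astype(np.float32)
    ys = (origin[1] + (np.arange(dims[1]) + 0.5) * voxel).astype(np.float32)
    zs = (origin[2] + (np.arange(dims[2]) + 0.5) * voxel).astype(np.float32)
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    def ellipsoid(cx, cy, cz, sa, sb, sc):
        return ((X - cx) / sa) ** 2 + ((Y - cy) / sb) ** 2 + ((Z - cz) / sc) ** 2 <= 1.0

    body = ellipsoid(0, 0, 0, a, b, c)
    inner = ellipsoid(0, 0, 0, a - t_skin, b - t_skin, c - t_skin)
    skin = body & ~inner

    ex, ey, ez = P["eye_center"]
    r_eye = P["eye_radius"] * L
    eyes = (ellipsoid(+ex * a, ey * b, ez * c, r_eye, r_eye, r_eye)
            | ellipsoid(-ex * a, ey * b, ez * c, r_eye, r_eye, r_eye))

    lx, ly, lz = P["lung_center"]
    sa, sb, sc = (P["lung_semiaxes"][0] * a, P["lung_semiaxes"][1] * b,
                  P["lung_semiaxes"][2] * c)
    lungs = (ellipsoid(+lx * a, ly * b, lz * c, sa, sb, sc)
             | ellipsoid(-lx * a, ly * b, lz * c, sa, sb, sc))

    r_sp = P["spine_radius"] * a
    spine = ((X ** 2 + (Y - P["spine_y"] * b) ** 2 <= r_sp ** 2)
             & (np.abs(Z) <= P["spine_halflength"] * c))
    r_limb = P["limb_radius"] * a
    y0, y1 = (P["limb_y"][0] * b, P["limb_y"][1] * b)
    limbs = np.zeros(tuple(dims), dtype=bool)
    for sx in (+1, -1):
        for sz in (+1, -1):
            cx = sx * P["limb_x"] * a
            cz = sz * P["limb_z"] * c
            limbs |= (((X - cx) ** 2 + (Z - cz) ** 2 <= r_limb ** 2)
                      & (Y >= y0) & (Y <= y1))
    bfo = spine | limbs

    # keep organs strictly inside the inner (sub-skin) body and disjoint
    eyes &= inner
    lungs &= inner & ~eyes
    bfo &= inner & ~eyes & ~lungs

    soft = get_material("soft_tissue")
    lung_m = get_material("lung")
    bone = get_material("bone")
    air = get_material("air")
    materials = [soft, lung_m, bone, air]
    mat_index = np.full(tuple(dims), 3, dtype=np.int16)  # air outside
    density = np.full(tuple(dims), air.density, dtype=np.float64)
    mat_index[body] = 0
    density[body] = soft.density
    mat_index[lungs] = 1
    density[lungs] = lung_m.density
    mat_index[bfo] = 2
    density[bfo] = bone.density

    grid = VoxelGrid(origin=origin, spacing=spacing, material_index=mat_index,
                     density=density, materials=materials)
    masks = {
        "BODY": StructureMask("BODY", body),
        "skin": StructureMask("skin", skin),
        "lungs": StructureMask("lungs", lungs),
        "BFO": StructureMask("BFO", bfo),
        "eyes": StructureMask("eyes", eyes),
    }
    return grid, masks
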