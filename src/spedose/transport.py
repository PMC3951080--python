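"""Condensed-history Monte Carlo transport in a voxelized world.

Each primary is stepped through the grid with step length
min(voxel-limited, range-limited, distance-to-voxel-boundary); mean energy
loss over a step comes from the CSDA range tables (exact table inversion, so
stopping depths reproduce the range oracle), with an optional Gaussian
straggling perturbation and Highland multiple scattering.  Outside the grid
particles fly in vacuum.  Electron radiative losses are computed and removed
but not deposited (photon transport is out of scope).

Every batch owns an independent, seeded random stream; within a batch each
history has its own counter-derived stream, which makes results independent
of history order and lets paired experiments share primaries (common random
numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from numba import njit

from .beams import BeamSpec, ParticleState, sample_primaries
from .geometry import VoxelGrid
from .materials import PhysicsTables

__all__ = ["TransportConfig", "DoseGrid", "run_transport", "run_batches",
           "combine_batches", "step_particle"]

MEV_TO_JOULE = 1.602176634e-13
# Gy per (MeV deposited / g): MeV->J divided by g->kg
GY_PER_MEV_PER_G = MEV_TO_JOULE * 1e3


@dataclass
class TransportConfig:
    """Stepping limits, cutoffs and batch bookkeeping for one simulation."""

    n_histories: int = 10_000
    n_batches: int = 1
    base_seed: int = 0
    max_step_fraction_of_voxel: float = 0.5
    max_step_fraction_of_range: float = 0.02
    min_step_cm: float = 0.005  # floor that tames the logarithmic step blow-up
    energy_cutoff: dict = dc_field(default_factory=lambda: {"proton": 1.0, "electron": 0.2})
    nuclear_attenuation_per_cm_water: float = 0.0  # optional fluence removal
    straggling: bool = True
    scattering: bool = True

    def __post_init__(self):
        for f in (self.max_step_fraction_of_voxel, self.max_step_fraction_of_range):
            if not 0 < f <= 1:
                raise ValueError("step fractions must lie in (0, 1]")
        for k, v in self.energy_cutoff.items():
            if v <= 0:
                raise ValueError(f"energy cutoff for {k} must be > 0")
        if self.n_histories < 0:
            raise ValueError("n_histories must be >= 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class DoseGrid:
    """Per-voxel dose (Gy per source particle) aligned to a VoxelGrid."""

    dose_mean: np.ndarray
    dose_sem: np.ndarray
    histories: int
    grid: VoxelGrid

    def __post_init__(self):
        if self.dose_mean.shape != self.grid.dims:
            raise ValueError("dose dims do not match grid")
        if np.any(self.dose_mean < 0) or np.any(self.dose_sem < 0):
            raise ValueError("dose and sem must be >= 0")

    def scaled(self, factor: float) -> "DoseGrid":
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return DoseGrid(self.dose_mean * factor, self.dose_sem * factor,
                        self.histories, self.grid)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _lerp_log(row, log_e0, inv_dlog_e, e):
    n = row.shape[0]
    x = (math.log(e) - log_e0) * inv_dlog_e
    if x <= 0.0:
        return row[0]
    if x >= n - 1:
        return row[n - 1]
    i = int(x)
    t = x - i
    return row[i] * (1.0 - t) + row[i + 1] * t


@njit(cache=True, inline="always")
def _energy_from_range(r_row, log_e0, dlog_e, r):
    """Invert the CSDA mass-range table; returns 0 when the particle stops."""
    n = r_row.shape[0]
    if r <= r_row[0]:
        return 0.0
    if r >= r_row[n - 1]:
        return math.exp(log_e0 + (n - 1) * dlog_e)
    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if r_row[mid] <= r:
            lo = mid
        else:
            hi = mid
    t = (math.log(r) - math.log(r_row[lo])) / (math.log(r_row[hi]) - math.log(r_row[lo]))
    return math.exp(log_e0 + (lo + t) * dlog_e)


@njit(cache=True, inline="always")
def _xorshift(s):
    s ^= s << np.uint64(13)
    s ^= s >> np.uint64(7)
    s ^= s << np.uint64(17)
    return s


@njit(cache=True)
def _aux_normals(state):
    """Two standard normals from a per-particle auxiliary stream (Box-Muller).

    Kept separate from the main stream so deterministic air traversals never
    shift the main stream's alignment between paired runs.
    """
    s = _xorshift(state)
    u1 = (np.float64(s >> np.uint64(11)) + 1.0) / 9007199254740993.0
    s = _xorshift(s)
    u2 = np.float64(s >> np.uint64(11)) / 9007199254740992.0
    r = math.sqrt(-2.0 * math.log(u1))
    return s, r * math.cos(2.0 * math.pi * u2), r * math.sin(2.0 * math.pi * u2)


@njit(cache=True)
def _transport_kernel(base_seed, pos, dirs, energy, weight,
                      mat, den, origin, spacing,
                      log_e0, dlog_e, s_rad, r_mass, inv_x0, k_str,
                      mass_mev, is_electron, ecut,
                      fvox, frange, min_step, kappa,
                      do_straggle, do_scatter, edep):
    nx, ny, nz = mat.shape
    ox, oy, oz = origin[0], origin[1], origin[2]
    dx, dy, dz = spacing[0], spacing[1], spacing[2]
    min_sp = min(dx, min(dy, dz))
    eps = 1e-4 * min_sp
    inv_dlog = 1.0 / dlog_e
    vox_step = fvox * min_sp

    e_dep = 0.0
    e_escaped = 0.0
    e_rad_total = 0.0
    e_nuc_total = 0.0

    npart = energy.shape[0]
    for pid in range(npart):
        np.random.seed((base_seed + pid * 48271) % 2147483647)
        x = pos[pid, 0]
        y = pos[pid, 1]
        z = pos[pid, 2]
        u = dirs[pid, 0]
        v = dirs[pid, 1]
        w = dirs[pid, 2]
        e = energy[pid]
        wt = weight[pid]
        # aggregated low-density (air) traversal bookkeeping
        air_xx0 = 0.0  # accumulated thickness in radiation lengths
        air_len = 0.0  # accumulated path, cm
        aux = ((np.uint64(base_seed + 1) * np.uint64(6364136223846793005)
                + np.uint64(pid + 1) * np.uint64(1442695040888963407))
               | np.uint64(1))

        for _ in range(4_000_000):
            if e <= 0.0:
                break
            ix = int(math.floor((x - ox) / dx))
            iy = int(math.floor((y - oy) / dy))
            iz = int(math.floor((z - oz) / dz))
            inside = (0 <= ix < nx) and (0 <= iy < ny) and (0 <= iz < nz)
            if not inside:
                # vacuum flight to the grid box (or escape)
                t0 = 0.0
                t1 = 1.0e30
                hit = True
                for ax in range(3):
                    if ax == 0:
                        p0, d0, lo, hi = x, u, ox, ox + nx * dx
                    elif ax == 1:
                        p0, d0, lo, hi = y, v, oy, oy + ny * dy
                    else:
                        p0, d0, lo, hi = z, w, oz, oz + nz * dz
                    if abs(d0) < 1e-12:
                        if p0 < lo or p0 > hi:
                            hit = False
                            break
                    else:
                        ta = (lo - p0) / d0
                        tb = (hi - p0) / d0
                        if ta > tb:
                            ta, tb = tb, ta
                        if ta > t0:
                            t0 = ta
                        if tb < t1:
                            t1 = tb
                if (not hit) or t1 <= t0 or t0 <= 0.0:
                    e_escaped += e * wt
                    break
                x += u * (t0 + eps)
                y += v * (t0 + eps)
                z += w * (t0 + eps)
                continue

            if e <= ecut:
                edep[ix, iy, iz] += e * wt
                e_dep += e * wt
                break

            m = mat[ix, iy, iz]
            rho = den[ix, iy, iz]

            if do_scatter and air_xx0 > 0.0 and rho >= 0.01:
                # leaving a low-density region: apply one aggregated Highland
                # deflection for the whole air path, displaced as if the kick
                # happened at the path midpoint (Fermi-Eyges-style lumping).
                pc = math.sqrt(e * (e + 2.0 * mass_mev))
                beta = pc / (e + mass_mev)
                corr = 1.0 + 0.038 * math.log(air_xx0)
                if corr < 0.25:
                    corr = 0.25
                sig_th = 13.6 / (beta * pc) * math.sqrt(air_xx0) * corr
                aux, g1, g2 = _aux_normals(aux)
                tx = sig_th * g1
                ty = sig_th * g2
                if abs(w) < 0.9:
                    nrm = math.sqrt(u * u + v * v)
                    e1x, e1y, e1z = v / nrm, -u / nrm, 0.0
                else:
                    nrm = math.sqrt(w * w + v * v)
                    e1x, e1y, e1z = 0.0, w / nrm, -v / nrm
                e2x = v * e1z - w * e1y
                e2y = w * e1x - u * e1z
                e2z = u * e1y - v * e1x
                half = 0.5 * air_len
                x += half * (tx * e1x + ty * e2x)
                y += half * (tx * e1y + ty * e2y)
                z += half * (tx * e1z + ty * e2z)
                u += tx * e1x + ty * e2x
                v += tx * e1y + ty * e2y
                w += tx * e1z + ty * e2z
                nrm = math.sqrt(u * u + v * v + w * w)
                u /= nrm
                v /= nrm
                w /= nrm
                air_xx0 = 0.0
                air_len = 0.0
                continue  # re-locate after the lateral displacement

            rres_mass = _lerp_log(r_mass[m], log_e0, inv_dlog, e)
            in_air = rho < 0.01  # near-vacuum: deterministic whole-voxel hops

            step = vox_step
            s2 = frange * rres_mass / rho
            if s2 < step:
                step = s2
            if step < min_step:
                step = min_step
            if in_air:
                step = 1.0e30  # boundary cap below sets the voxel-exit step
            # distance to the voxel boundary along the flight direction
            tb = 1.0e30
            if u > 1e-12:
                t = ((ix + 1) * dx + ox - x) / u
            elif u < -1e-12:
                t = (ix * dx + ox - x) / u
            else:
                t = 1.0e30
            if t < tb:
                tb = t
            if v > 1e-12:
                t = ((iy + 1) * dy + oy - y) / v
            elif v < -1e-12:
                t = (iy * dy + oy - y) / v
            else:
                t = 1.0e30
            if t < tb:
                tb = t
            if w > 1e-12:
                t = ((iz + 1) * dz + oz - z) / w
            elif w < -1e-12:
                t = (iz * dz + oz - z) / w
            else:
                t = 1.0e30
            if t < tb:
                tb = t
            if tb < 0.0:
                tb = 0.0
            if step > tb:
                step = tb + eps

            # mean energy loss from the range tables (exact CSDA inversion)
            rnew = rres_mass - rho * step
            enew_mean = _energy_from_range(r_mass[m], log_e0, dlog_e, rnew)
            de_mean = e - enew_mean
            if de_mean < 0.0:
                de_mean = 0.0
            de = de_mean
            if do_straggle and not in_air and de_mean > 0.0 and de_mean < e:
                sig = math.sqrt(k_str[m] * rho * step)
                lim = 3.0 * sig
                if de_mean < lim:
                    lim = de_mean
                if e - de_mean < lim:
                    lim = e - de_mean
                delta = sig * np.random.standard_normal()
                if delta > lim:
                    delta = lim
                elif delta < -lim:
                    delta = -lim
                de = de_mean + delta
            if de > e:
                de = e

            erad = 0.0
            if is_electron:
                erad = _lerp_log(s_rad[m], log_e0, inv_dlog, e) * rho * step
                if erad > e - de:
                    erad = e - de

            edep[ix, iy, iz] += de * wt
            e_dep += de * wt
            e_rad_total += erad * wt
            e = e - de - erad

            if kappa > 0.0 and not is_electron:
                surv = math.exp(-kappa * rho * step)
                if np.random.random() > surv:
                    e_nuc_total += e * wt
                    e = 0.0
                    break

            x += u * step
            y += v * step
            z += w * step

            if e <= ecut:
                edep[ix, iy, iz] += e * wt
                e_dep += e * wt
                break

            if in_air:
                air_xx0 += step * rho * inv_x0[m]
                air_len += step
                continue

            if do_scatter:
                xx0 = step * rho * inv_x0[m]
                pc = math.sqrt(e * (e + 2.0 * mass_mev))
                beta = pc / (e + mass_mev)
                corr = 1.0 + 0.038 * math.log(xx0)
                if corr < 0.25:
                    corr = 0.25
                sig_th = 13.6 / (beta * pc) * math.sqrt(xx0) * corr
                tx = sig_th * np.random.standard_normal()
                ty = sig_th * np.random.standard_normal()
                # transverse basis
                if abs(w) < 0.9:
                    # e1 = dir x z-hat (normalized)
                    nrm = math.sqrt(u * u + v * v)
                    e1x, e1y, e1z = v / nrm, -u / nrm, 0.0
                else:
                    nrm = math.sqrt(w * w + v * v)
                    e1x, e1y, e1z = 0.0, w / nrm, -v / nrm
                # e2 = dir x e1
                e2x = v * e1z - w * e1y
                e2y = w * e1x - u * e1z
                e2z = u * e1y - v * e1x
                u += tx * e1x + ty * e2x
                v += tx * e1y + ty * e2y
                w += tx * e1z + ty * e2z
                nrm = math.sqrt(u * u + v * v + w * w)
                u /= nrm
                v /= nrm
                w /= nrm

    return e_dep, e_escaped, e_rad_total, e_nuc_total


# ---------------------------------------------------------------------------
# python driver
# ---------------------------------------------------------------------------

def _physics_for(grid: VoxelGrid, particle: str) -> PhysicsTables:
    return PhysicsTables(grid.materials, particle)


def run_transport(grid: VoxelGrid, beam: BeamSpec, cfg: TransportConfig,
                  seed: int, return_stats: bool = False):
    """Transport one batch of ``cfg.n_histories`` primaries; score dose.

    Deterministic given (seed, cfg, beam, grid).  Returns a single-batch
    :class:`DoseGrid` (sem = 0); pass ``return_stats=True`` to also get the
    energy bookkeeping dict (deposited / escaped / radiative / nuclear, MeV).
    """
    n = cfg.n_histories
    edep = np.zeros(grid.dims, dtype=np.float64)
    stats = {"deposited": 0.0, "escaped": 0.0, "radiative": 0.0,
             "nuclear": 0.0, "initial": 0.0}
    if n > 0:
        rng = np.random.default_rng(seed)
        pos, dirs, energy, weight = sample_primaries(rng, beam, grid, n)
        stats["initial"] = float((energy * weight).sum())
        tables = _physics_for(grid, beam.particle)
        ecut = cfg.energy_cutoff[beam.particle]
        kernel_seed = (seed * 2654435761 + 12345) % 2147483629
        out = _transport_kernel(
            kernel_seed,
            np.ascontiguousarray(pos), np.ascontiguousarray(dirs),
            np.ascontiguousarray(energy), np.ascontiguousarray(weight),
            np.ascontiguousarray(grid.material_index.astype(np.int16)),
            np.ascontiguousarray(grid.density.astype(np.float64)),
            grid.origin, grid.spacing,
            tables.log_e0, tables.dlog_e,
            tables.s_rad, tables.r_mass, tables.inv_x0, tables.k_str,
            tables.mass_mev, beam.particle == "electron", ecut,
            cfg.max_step_fraction_of_voxel, cfg.max_step_fraction_of_range,
            cfg.min_step_cm, cfg.nuclear_attenuation_per_cm_water,
            cfg.straggling, cfg.scattering, edep)
        stats["deposited"], stats["escaped"], stats["radiative"], stats["nuclear"] = map(float, out)
    mass = grid.voxel_mass()  # g
    dose = np.where(mass > 0, edep * GY_PER_MEV_PER_G / mass, 0.0)
    if n > 0:
        dose /= n
    result = DoseGrid(dose_mean=dose, dose_sem=np.zeros_like(dose),
                      histories=n, grid=grid)
    return (result, stats) if return_stats else result


def run_batches(grid: VoxelGrid, beam: BeamSpec, cfg: TransportConfig) -> DoseGrid:
    """Run ``cfg.n_batches`` independently seeded batches and combine them."""
    batches = [run_transport(grid, beam, cfg, seed=cfg.base_seed + k)
               for k in range(cfg.n_batches)]
    if len(batches) == 1:
        return batches[0]
    return combine_batches(batches)


def combine_batches(batches: list) -> DoseGrid:
    """Per-voxel mean over batches; sem = batch std / sqrt(n_batches).

    The batch standard deviation is the population form (ddof=0), so two
    batches {D, 3D} give sem = D/sqrt(2).
    """
    if len(batches) < 2:
        raise ValueError("need at least 2 batches to combine")
    g0 = batches[0].grid
    for b in batches[1:]:
        if b.dose_mean.shape != batches[0].dose_mean.shape:
            raise ValueError("batch dims mismatch")
        if b.grid is not g0 and not (
                np.allclose(b.grid.origin, g0.origin)
                and np.allclose(b.grid.spacing, g0.spacing)):
            raise ValueError("batch grid alignment mismatch")
    stack = np.stack([b.dose_mean for b in batches])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0) / math.sqrt(len(batches))
    return DoseGrid(dose_mean=mean, dose_sem=sem,
                    histories=sum(b.histories for b in batches), grid=g0)


# ---------------------------------------------------------------------------
# single-step reference (python, for inspection and unit checks)
# ---------------------------------------------------------------------------

def step_particle(state: ParticleState, grid: VoxelGrid, cfg: TransportConfig,
                  rng: np.random.Generator):
    """Advance one condensed-history step; returns (state', [(ijk, MeV)]).

    A plain-python mirror of one kernel iteration built on the public physics
    functions — convenient for inspecting the stepping logic and for tests.
    Particles outside the grid are flown in vacuum to the grid (or escape,
    returning energy 0 deposits).
    """
    from .materials import csda_range, scattering_sigma, straggling_sigma

    p = state.position.copy()
    d = state.direction.copy()
    e = state.energy
    lo, hi = grid.extent
    ijk = np.floor((p - grid.origin) / grid.spacing).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.array(grid.dims)))
    if not inside:
        with np.errstate(divide="ignore"):
            t_lo = np.where(np.abs(d) > 1e-12, (lo - p) / d, -np.inf)
            t_hi = np.where(np.abs(d) > 1e-12, (hi - p) / d, np.inf)
        t0 = float(np.max(np.minimum(t_lo, t_hi)))
        t1 = float(np.min(np.maximum(t_lo, t_hi)))
        slab_ok = np.all((np.abs(d) > 1e-12) | ((p >= lo) & (p <= hi)))
        if (not slab_ok) or t1 <= t0 or t0 <= 0:
            return ParticleState(p + d * 1e6, d, e, state.kind, state.weight), []
        eps = 1e-4 * grid.spacing.min()
        return ParticleState(p + d * (t0 + eps), d, e, state.kind, state.weight), []

    ecut = cfg.energy_cutoff[state.kind]
    i, j, k = (int(a) for a in ijk)
    if e <= ecut:
        # residual deposited locally at termination
        return (ParticleState(p, d, 1e-30, state.kind, state.weight),
                [((i, j, k), e)])
    mat = grid.materials[grid.material_index[i, j, k]]
    rho = float(grid.density[i, j, k])
    mat_here = mat.with_density(rho)
    rres = csda_range(mat_here, state.kind, e)
    step = min(cfg.max_step_fraction_of_voxel * grid.spacing.min(),
               cfg.max_step_fraction_of_range * rres)
    step = max(step, cfg.min_step_cm)
    bounds = grid.origin + (ijk + (d > 0)) * grid.spacing
    with np.errstate(divide="ignore"):
        tb = np.where(np.abs(d) > 1e-12, (bounds - p) / d, np.inf)
    tb_min = float(max(np.min(tb), 0.0))
    eps = 1e-4 * grid.spacing.min()
    if step > tb_min:
        step = tb_min + eps

    from .materials import _cached_range_table  # exact CSDA inversion
    egrid, rtab = _cached_range_table(mat_here, state.kind)
    r_here = np.exp(np.interp(np.log(np.clip(e, egrid[0], egrid[-1])),
                              np.log(egrid), np.log(rtab)))
    rnew = r_here - rho * step
    if rnew <= rtab[0]:
        de_mean = e
    else:
        enew = np.exp(np.interp(np.log(rnew), np.log(rtab), np.log(egrid)))
        de_mean = max(e - float(enew), 0.0)
    de = de_mean
    if cfg.straggling and 0 < de_mean < e:
        sig = straggling_sigma(mat_here, state.kind, e, step)
        lim = min(3 * sig, de_mean, e - de_mean)
        de = de_mean + float(np.clip(sig * rng.standard_normal(), -lim, lim))
    de = min(de, e)
    erad = 0.0
    if state.kind == "electron":
        from .materials import radiative_stopping_power
        erad = min(float(radiative_stopping_power(mat_here, e)) * step, e - de)
    e_new = e - de - erad
    p_new = p + d * step
    d_new = d
    if cfg.scattering and e_new > ecut:
        sig_th = scattering_sigma(mat_here, state.kind, e_new, step)
        tx, ty = sig_th * rng.standard_normal(2)
        ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(d, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        d_new = d + tx * e1 + ty * e2
        d_new /= np.linalg.norm(d_new)
    deposits = [((i, j, k), de)]
    if e_new <= ecut and e_new > 0:
        deposits.append(((i, j, k), e_new))
        e_new = 0.0
    return ParticleState(p_new, d_new, max(e_new, 1e-30), state.kind, state.weight), deposits
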