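"""Primary-particle sources: the large-field electron beam and the broad
parallel SPE proton beam.

The electron source is a circular planar disc (2 cm radius) 1 m upstream of
the machine isocenter; each primary aims at a point drawn uniformly on the
square collimator aperture in the isocenter plane (34 cm x 34 cm by default),
so every isocenter-plane crossing lies inside the aperture by construction.
The phantom entrance face sits at the configured SSD from the source.  The
proton beam is a parallel beam with energies drawn from a discrete spectrum.

Beam angles are restricted to the four cardinal angles about the grid's long
(z) axis: 0 deg -> +x, 90 deg -> +y, 180 deg -> -x, 270 deg -> -y.  Rotating
the angle rotates the source assembly; the grid is never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import VoxelGrid
from .unfold import Spectrum

__all__ = ["BeamSpec", "ParticleState", "beam_axis",
           "sample_electron_primary", "sample_proton_primary",
           "sample_primaries"]

_AXIS_BY_ANGLE = {0: np.array([1.0, 0.0, 0.0]),
                  90: np.array([0.0, 1.0, 0.0]),
                  180: np.array([-1.0, 0.0, 0.0]),
                  270: np.array([0.0, -1.0, 0.0])}


@dataclass
class BeamSpec:
    """Source description for one beam.

    For electrons give (nominal_energy, relative_spread); for protons give a
    :class:`~spedose.unfold.Spectrum` (or a single-line spectrum) and set
    ``parallel=True``.  ``clip_halfwidth_at_isocenter`` is half the square
    aperture edge in the isocenter plane; ``aim_halfwidth`` optionally
    restricts the *sampled* aim points to a sub-window of the aperture (an
    importance restriction for small scoring regions — the full-field primary
    phase space restricted to near-axis rays).
    """

    particle: str  # 'proton' | 'electron'
    nominal_energy: float = 0.0  # MeV (electron mode)
    relative_spread: float = 0.0  # sigma as a fraction of nominal
    spectrum: Optional[Spectrum] = None  # proton mode
    source_radius: float = 2.0  # cm
    source_to_isocenter: float = 100.0  # cm
    clip_halfwidth_at_isocenter: float = 17.0  # cm (34 x 34 cm field)
    ssd: float = 500.0  # cm source-to-surface distance
    angle: int = 0  # degrees, one of {0, 90, 180, 270}
    parallel: bool = False
    field_margin: float = 2.0  # cm beyond the entrance face (parallel beams)
    field_halfwidth: Optional[float] = None  # cm; overrides face+margin
    aim_halfwidth: Optional[float] = None  # cm at the entrance plane
    spread_is_sigma: bool = True  # "10% Gaussian spread" read as sigma, not FWHM

    def __post_init__(self):
        if self.angle not in _AXIS_BY_ANGLE:
            raise ValueError("angle must be one of 0, 90, 180, 270 degrees")
        if self.particle not in ("proton", "electron"):
            raise ValueError(f"unknown particle {self.particle!r}")
        if self.spectrum is not None:
            w = np.asarray(self.spectrum.weights, dtype=float)
            if np.any(w < 0):
                raise ValueError("spectrum weights must be >= 0")
            if w.sum() <= 0:
                raise ValueError("all-zero spectrum")


@dataclass
class ParticleState:
    """Position (cm), unit direction, kinetic energy (MeV), statistical weight."""

    position: np.ndarray
    direction: np.ndarray
    energy: float
    kind: str
    weight: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.energy <= 0:
            raise ValueError("energy must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


def beam_axis(angle: int) -> np.ndarray:
    """Unit beam direction for a cardinal angle about the z (crown-rump) axis."""
    return _AXIS_BY_ANGLE[angle].copy()


def _beam_frame(spec: BeamSpec, grid: VoxelGrid):
    """Return (d, e1, e2, entrance_point).

    d is the beam direction; e1, e2 span the transverse plane (e2 = z axis);
    entrance_point is the beam-axis piercing point of the upstream grid face.
    """
    d = beam_axis(spec.angle)
    e2 = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(e2, d)
    lo, hi = grid.extent
    c = grid.center
    entrance = c.copy()
    ax = int(np.argmax(np.abs(d)))
    entrance[ax] = lo[ax] if d[ax] > 0 else hi[ax]
    return d, e1, e2, entrance


def _sample_disc(rng: np.random.Generator, n: int, radius: float):
    r = radius * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    return r * np.cos(phi), r * np.sin(phi)


def _sample_truncated_normal(rng, n, mean, sigma):
    e = rng.normal(mean, sigma, size=n)
    bad = e <= 0
    while bad.any():
        e[bad] = rng.normal(mean, sigma, size=int(bad.sum()))
        bad = e <= 0
    return e


def sample_electron_primaries(rng: np.random.Generator, spec: BeamSpec,
                              grid: VoxelGrid, n: int):
    """Vectorized electron source sampling; returns (pos, dir, energy, weight)."""
    d, e1, e2, entrance = _beam_frame(spec, grid)
    src_center = entrance - d * spec.ssd
    iso_dist = spec.source_to_isocenter
    h = spec.clip_halfwidth_at_isocenter
    mag = spec.ssd / iso_dist  # aperture magnification at the entrance plane

    if spec.aim_halfwidth is not None:
        # restrict to primaries whose straight-ray surface crossing lies within
        # +-aim_halfwidth of the axis; exact subset of the full-field source
        win = min(spec.aim_halfwidth, h * mag)
    else:
        win = None

    sx, sy = _sample_disc(rng, n, spec.source_radius)
    if win is not None and (win + spec.source_radius * (mag - 1.0)) / mag <= h:
        # The straight-ray surface crossing is c = a*mag - s*(mag-1); for any
        # source point s the aim points giving |c| <= win form an interval of
        # constant length inside the aperture, so sampling c directly yields
        # exactly the full-field phase space restricted to |c| <= win with
        # uniform statistical weights.
        cx = rng.uniform(-win, win, size=n)
        cy = rng.uniform(-win, win, size=n)
        ax_ = (cx + sx * (mag - 1.0)) / mag
        ay_ = (cy + sy * (mag - 1.0)) / mag
    else:
        ax_ = rng.uniform(-h, h, size=n)
        ay_ = rng.uniform(-h, h, size=n)
        if win is not None:
            # rare fallback: rejection against the crossing window
            while True:
                cx = ax_ * mag - sx * (mag - 1.0)
                cy = ay_ * mag - sy * (mag - 1.0)
                bad = (np.abs(cx) > win) | (np.abs(cy) > win)
                if not bad.any():
                    break
                m = int(bad.sum())
                bx, by = _sample_disc(rng, m, spec.source_radius)
                sx[bad], sy[bad] = bx, by
                ax_[bad] = rng.uniform(-h, h, size=m)
                ay_[bad] = rng.uniform(-h, h, size=m)
    pos = src_center + np.outer(sx, e1) + np.outer(sy, e2)
    aim = src_center + d * iso_dist + np.outer(ax_, e1) + np.outer(ay_, e2)
    dirs = aim - pos
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]

    sigma = spec.relative_spread * spec.nominal_energy
    if not spec.spread_is_sigma:
        sigma /= 2.3548200450309493  # FWHM -> sigma
    if sigma > 0:
        energy = _sample_truncated_normal(rng, n, spec.nominal_energy, sigma)
    else:
        energy = np.full(n, spec.nominal_energy)
    return pos, dirs, energy, np.ones(n)


def sample_proton_primaries(rng: np.random.Generator, spec: BeamSpec,
                            grid: VoxelGrid, n: int):
    """Broad parallel proton beam over the entrance face (+ margin)."""
    if not spec.parallel:
        raise ValueError("proton source must be parallel")
    if spec.spectrum is None:
        raise ValueError("proton source needs a spectrum")
    d, e1, e2, entrance = _beam_frame(spec, grid)
    lo, hi = grid.extent
    half = np.abs(hi - lo) / 2.0
    if spec.field_halfwidth is not None:
        h1 = h2 = spec.field_halfwidth
    else:
        h1 = float(np.abs(e1) @ half) + spec.field_margin
        h2 = float(np.abs(e2) @ half) + spec.field_margin
    u1 = rng.uniform(-h1, h1, size=n)
    u2 = rng.uniform(-h2, h2, size=n)
    start = entrance - d * 0.5  # just upstream; vacuum outside the grid
    pos = start + np.outer(u1, e1) + np.outer(u2, e2)
    dirs = np.tile(d, (n, 1))
    en = np.asarray(spec.spectrum.energies, dtype=float)
    w = np.asarray(spec.spectrum.weights, dtype=float)
    p = w / w.sum()
    energy = en[rng.choice(len(en), size=n, p=p)]
    return pos, dirs, energy, np.ones(n)


def sample_primaries(rng: np.random.Generator, spec: BeamSpec,
                     grid: VoxelGrid, n: int):
    if spec.particle == "electron":
        return sample_electron_primaries(rng, spec, grid, n)
    return sample_proton_primaries(rng, spec, grid, n)


def sample_electron_primary(rng: np.random.Generator, spec: BeamSpec,
                            grid: VoxelGrid) -> ParticleState:
    """Sample a single electron primary (see :func:`sample_electron_primaries`)."""
    pos, dirs, e, w = sample_electron_primaries(rng, spec, grid, 1)
    return ParticleState(pos[0], dirs[0], float(e[0]), "electron", float(w[0]))


def sample_proton_primary(rng: np.random.Generator, spec: BeamSpec,
                          grid: VoxelGrid) -> ParticleState:
    """Sample a single proton primary (see :func:`sample_proton_primaries`)."""
    pos, dirs, e, w = sample_proton_primaries(rng, spec, grid, 1)
    return ParticleState(pos[0], dirs[0], float(e[0]), "proton", float(w[0]))
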