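"""Material definitions, HU conversion, and charged-particle physics tables.

The transport engine needs, for every medium, collision (and for electrons
radiative) stopping power, CSDA range, a multiple-scattering radiation length
and a Gaussian energy-straggling coefficient.  Protons use the Bethe formula
without shell or density corrections; electrons use the Berger–Seltzer
collision formula (Møller cross-section).  Both are adequate over the bands
this package targets (protons 1–150 MeV, electrons 0.1–30 MeV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "Material",
    "HUConversionTable",
    "BUILTIN_MATERIALS",
    "get_material",
    "collision_stopping_power",
    "radiative_stopping_power",
    "csda_range",
    "scattering_sigma",
    "straggling_sigma",
    "hu_to_material",
    "default_hu_table",
    "PhysicsTables",
]

ELECTRON_MASS_MEV = 0.51099895
PROTON_MASS_MEV = 938.27208816
# Bethe coefficient 4*pi*N_A*r_e^2*m_e*c^2 [MeV cm^2 / mol]
K_BETHE = 0.307075
# Bohr straggling: sigma^2 = BOHR_COEFF * (Z/A) * rho * t  [MeV^2], t in cm
BOHR_COEFF = 0.1569

# element symbol -> (Z, A [g/mol], I [eV])
ELEMENTS = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "Na": (11, 22.990, 149.0),
    "Mg": (12, 24.305, 156.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "Ar": (18, 39.948, 188.0),
    "K": (19, 39.098, 190.0),
    "Ca": (20, 40.078, 191.0),
    "Fe": (26, 55.845, 286.0),
}


def _tsai_x0(z: int, a: float) -> float:
    """Approximate radiation length of one element, g/cm^2."""
    return 716.408 * a / (z * (z + 1) * math.log(287.0 / math.sqrt(z)))


@dataclass(frozen=True)
class Material:
    """A homogeneous medium: elemental mass fractions plus bulk parameters.

    ``mean_excitation_energy`` (eV) and ``radiation_length`` (g/cm^2) are
    derived from the composition via Bragg additivity / Tsai's formula when
    not given explicitly.
    """

    name: str
    composition: dict  # element symbol -> mass fraction
    density: float  # g/cm^3 (reference density)
    mean_excitation_energy: float = 0.0  # eV; 0 -> derive
    radiation_length: float = 0.0  # g/cm^2; 0 -> derive

    def __post_init__(self):
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, not 1")
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")
        for el in self.composition:
            if el not in ELEMENTS:
                raise ValueError(f"{self.name}: unknown element {el!r}")
        if self.mean_excitation_energy == 0.0:
            object.__setattr__(self, "mean_excitation_energy", self._bragg_i())
        if self.mean_excitation_energy <= 0:
            raise ValueError(f"{self.name}: mean excitation energy must be > 0")
        if self.radiation_length == 0.0:
            inv = sum(w / _tsai_x0(*ELEMENTS[el][:2]) for el, w in self.composition.items())
            object.__setattr__(self, "radiation_length", 1.0 / inv)

    def _bragg_i(self) -> float:
        num = den = 0.0
        for el, w in self.composition.items():
            z, a, i = ELEMENTS[el]
            num += w * z / a * math.log(i)
            den += w * z / a
        return math.exp(num / den)

    @property
    def z_over_a(self) -> float:
        """Mean Z/A of the mixture (mol/g ... dimensionless per nucleon)."""
        return sum(w * ELEMENTS[el][0] / ELEMENTS[el][1] for el, w in self.composition.items())

    @property
    def z_eff(self) -> float:
        # ionization-weighted effective Z, used only for the crude radiative term
        num = sum(w * ELEMENTS[el][0] ** 2 / ELEMENTS[el][1] for el, w in self.composition.items())
        return num / self.z_over_a

    def with_density(self, density: float) -> "Material":
        return Material(self.name, dict(self.composition), density,
                        self.mean_excitation_energy, self.radiation_length)


def _builtin_materials() -> dict:
    mats = [
        Material("water", {"H": 0.111894, "O": 0.888106}, 1.0,
                 mean_excitation_energy=75.0),
        Material("air", {"C": 0.000124, "N": 0.755268, "O": 0.231781, "Ar": 0.012827},
                 1.20479e-3, mean_excitation_energy=85.7),
        # Gammex Solid Water; density is the vendor-standard 1.04 g/cm^3
        Material("solid_water",
                 {"H": 0.0809, "C": 0.6717, "N": 0.0241, "O": 0.1988,
                  "Cl": 0.0014, "Ca": 0.0231}, 1.04),
        Material("pmma", {"H": 0.080538, "C": 0.599848, "O": 0.319614}, 1.19,
                 mean_excitation_energy=74.0),
        Material("soft_tissue",
                 {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708, "Na": 0.002,
                  "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003}, 1.00),
        Material("adipose",
                 {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278, "Na": 0.001,
                  "S": 0.001, "Cl": 0.001}, 0.95),
        Material("muscle",
                 {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710, "Na": 0.001,
                  "P": 0.002, "S": 0.003, "Cl": 0.001, "K": 0.004}, 1.05),
        Material("lung",
                 {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "Na": 0.002,
                  "P": 0.002, "S": 0.003, "Cl": 0.003, "K": 0.002}, 0.30),
        Material("bone",
                 {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
                  "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}, 1.40),
    ]
    return {m.name: m for m in mats}


BUILTIN_MATERIALS = _builtin_materials()


def get_material(name: str) -> Material:
    try:
        return BUILTIN_MATERIALS[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; built-ins: {sorted(BUILTIN_MATERIALS)}")


# ---------------------------------------------------------------------------
# stopping power / range / scattering / straggling
# ---------------------------------------------------------------------------

PROTON_VALIDITY_FLOOR_MEV = 1.0
ELECTRON_VALIDITY_FLOOR_MEV = 0.01


def _kinematics(energy: float, mass: float):
    gamma = 1.0 + energy / mass
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    return gamma, beta2


def _proton_mass_sp(material: Material, energy) -> np.ndarray:
    """Bethe collision mass stopping power, MeV cm^2/g (no shell/density corr.)."""
    e = np.asarray(energy, dtype=float)
    gamma = 1.0 + e / PROTON_MASS_MEV
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    i_mev = material.mean_excitation_energy * 1e-6
    arg = 2.0 * ELECTRON_MASS_MEV * beta2 * gamma * gamma / i_mev
    log_term = np.log(np.maximum(arg, 1.0 + 1e-12))
    return K_BETHE * material.z_over_a / beta2 * (log_term - beta2)


def _electron_mass_sp(material: Material, energy) -> np.ndarray:
    """Berger–Seltzer collision mass stopping power, MeV cm^2/g (no density corr.)."""
    e = np.asarray(energy, dtype=float)
    tau = e / ELECTRON_MASS_MEV
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    i_ratio = material.mean_excitation_energy * 1e-6 / ELECTRON_MASS_MEV
    f_minus = (1.0 - beta2
               + (tau * tau / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / (gamma * gamma))
    arg = tau * tau * (tau + 2.0) / (2.0 * i_ratio * i_ratio)
    return 0.5 * K_BETHE * material.z_over_a / beta2 * (np.log(np.maximum(arg, 1.0 + 1e-12)) + f_minus)


def collision_stopping_power(material: Material, particle: str, energy: float) -> float:
    """Collision stopping power in MeV/cm at the material's density.

    Scales linearly with density at fixed composition.  Rejects energies at or
    below the particle's validity floor.
    """
    floor = PROTON_VALIDITY_FLOOR_MEV if particle == "proton" else ELECTRON_VALIDITY_FLOOR_MEV
    if np.any(np.asarray(energy) < floor) or np.any(np.asarray(energy) <= 0):
        raise ValueError(f"energy below validity floor ({floor} MeV) for {particle}")
    if particle == "proton":
        sp = _proton_mass_sp(material, energy)
    elif particle == "electron":
        sp = _electron_mass_sp(material, energy)
    else:
        raise ValueError(f"unknown particle {particle!r}")
    return float(sp * material.density) if np.isscalar(energy) else sp * material.density


def radiative_stopping_power(material: Material, energy) -> np.ndarray:
    """Crude electron radiative stopping power, MeV/cm.

    Uses the rule-of-thumb ratio S_rad/S_col ≈ T·Z_eff/700 (T in MeV); good to
    ~20% in the 1–30 MeV band, where radiative losses are a few-percent
    correction.  The transport engine removes (does not deposit) this energy.
    """
    e = np.asarray(energy, dtype=float)
    return _electron_mass_sp(material, e) * (e * material.z_eff / 700.0) * material.density


def _total_mass_sp(material: Material, particle: str, energy) -> np.ndarray:
    e = np.asarray(energy, dtype=float)
    if particle == "proton":
        return _proton_mass_sp(material, e)
    sp = _electron_mass_sp(material, e)
    return sp * (1.0 + e * material.z_eff / 700.0)


_EGRID_N = 800
_EGRID_BOUNDS = {"proton": (0.05, 250.0), "electron": (0.01, 50.0)}


def _range_table(material: Material, particle: str):
    """(egrid, R[g/cm^2]) CSDA mass range on a dense log grid."""
    lo, hi = _EGRID_BOUNDS[particle]
    egrid = np.geomspace(lo, hi, _EGRID_N)
    sp = _total_mass_sp(material, particle, egrid)
    sp = np.maximum(sp, 1e-12)
    inv = 1.0 / sp
    r = np.concatenate([[egrid[0] * inv[0]],  # approximate residual below the grid
                        np.zeros(_EGRID_N - 1)])
    r[1:] = r[0] + np.cumsum(0.5 * (inv[1:] + inv[:-1]) * np.diff(egrid))
    return egrid, r


_RANGE_CACHE: dict = {}


def _cached_range_table(material: Material, particle: str):
    key = (material.name, round(material.density, 9),
           round(material.mean_excitation_energy, 6), particle)
    if key not in _RANGE_CACHE:
        _RANGE_CACHE[key] = _range_table(material, particle)
    return _RANGE_CACHE[key]


def csda_range(material: Material, particle: str, energy: float) -> float:
    """Continuous-slowing-down range in cm (log-log interpolated table lookup)."""
    if energy < 0:
        raise ValueError("energy must be >= 0")
    if energy == 0:
        return 0.0
    egrid, r = _cached_range_table(material, particle)
    e = min(max(energy, egrid[0]), egrid[-1])
    rr = np.exp(np.interp(np.log(e), np.log(egrid), np.log(r)))
    return float(rr / material.density)


def scattering_sigma(material: Material, particle: str, energy: float, step: float) -> float:
    """Highland small-angle multiple-scattering sigma (radians) over one step."""
    if step <= 0:
        raise ValueError("step must be > 0")
    mass = PROTON_MASS_MEV if particle == "proton" else ELECTRON_MASS_MEV
    gamma, beta2 = _kinematics(energy, mass)
    pc = math.sqrt(energy * (energy + 2.0 * mass))
    beta = math.sqrt(beta2)
    x_over_x0 = step * material.density / material.radiation_length
    corr = max(1.0 + 0.038 * math.log(x_over_x0), 0.25)
    return 13.6 / (beta * pc) * math.sqrt(x_over_x0) * corr


def straggling_sigma(material: Material, particle: str, energy: float, step: float) -> float:
    """Gaussian (Bohr) energy-loss straggling sigma in MeV over one step."""
    if step <= 0:
        raise ValueError("step must be > 0")
    return math.sqrt(BOHR_COEFF * material.z_over_a * material.density * step)


# ---------------------------------------------------------------------------
# HU conversion
# ---------------------------------------------------------------------------

@dataclass
class HUConversionTable:
    """Contiguous HU bins, each mapping to a material and an affine density model.

    ``entries`` is an ordered list of (hu_low, hu_high, material_name,
    (intercept, slope)) with density = intercept + slope*HU in g/cm^3.
    A HU value exactly on a shared boundary belongs to the lower bin.
    """

    entries: list = field(default_factory=list)

    def __post_init__(self):
        if not self.entries:
            raise ValueError("HU conversion table is empty")
        for k in range(len(self.entries) - 1):
            if self.entries[k][1] != self.entries[k + 1][0]:
                raise ValueError("HU bins must be contiguous and non-overlapping")
        for lo, hi, name, (b, m) in self.entries:
            get_material(name)
            for hu in (lo, hi):
                if b + m * hu <= 0:
                    raise ValueError(f"density model yields non-positive density at HU {hu}")

    @property
    def materials(self) -> list:
        return [e[2] for e in self.entries]

    def lookup(self, hu: float):
        lo = self.entries[0][0]
        hi = self.entries[-1][1]
        hu = min(max(hu, lo), hi)
        # boundary HU -> lower bin
        edges = [e[1] for e in self.entries[:-1]]
        idx = int(np.searchsorted(edges, hu, side="left"))
        b, m = self.entries[idx][3]
        return idx, max(b + m * hu, 1e-6)


def default_hu_table() -> HUConversionTable:
    """Minimal 4-bin table: air < -950 < lung < -200 < soft tissue < +120 < bone.

    Density ramps are piecewise affine and monotone across the supported span
    (-1000 .. +2000 HU); a finer user-supplied table is accepted wherever a
    table is taken.
    """
    return HUConversionTable(entries=[
        (-1000.0, -950.0, "air", (1.20479e-3, 0.0)),
        (-950.0, -200.0, "lung", (1.0, 1.0e-3)),
        (-200.0, 120.0, "soft_tissue", (1.0, 1.0e-3)),
        (120.0, 2000.0, "bone", (1.048, 6.0e-4)),
    ])


def hu_to_material(hu: float, table: HUConversionTable):
    """Map one HU value to (material_index, density g/cm^3) via the table."""
    return table.lookup(hu)


# ---------------------------------------------------------------------------
# packed tables for the transport kernel
# ---------------------------------------------------------------------------

class PhysicsTables:
    """Per-material physics tables sampled on a uniform log-energy grid.

    Consumed directly by the numba transport kernel: collision / radiative
    stopping power (MeV cm^2/g), CSDA mass range (g/cm^2), inverse radiation
    length (cm^2/g) and the Bohr straggling coefficient per material.
    """

    def __init__(self, materials: list, particle: str, n_knots: int = 400):
        self.particle = particle
        self.materials = list(materials)
        self.mass_mev = PROTON_MASS_MEV if particle == "proton" else ELECTRON_MASS_MEV
        lo, hi = _EGRID_BOUNDS[particle]
        self.egrid = np.geomspace(lo, hi, n_knots)
        self.log_e0 = math.log(lo)
        self.dlog_e = math.log(hi / lo) / (n_knots - 1)
        nm = len(self.materials)
        self.s_col = np.empty((nm, n_knots))
        self.s_rad = np.zeros((nm, n_knots))
        self.r_mass = np.empty((nm, n_knots))
        self.inv_x0 = np.empty(nm)
        self.k_str = np.empty(nm)
        for i, mat in enumerate(self.materials):
            if particle == "proton":
                self.s_col[i] = _proton_mass_sp(mat, self.egrid)
            else:
                self.s_col[i] = _electron_mass_sp(mat, self.egrid)
                self.s_rad[i] = self.s_col[i] * self.egrid * mat.z_eff / 700.0
            eg, r = _cached_range_table(mat, particle)
            self.r_mass[i] = np.exp(np.interp(np.log(self.egrid), np.log(eg), np.log(r)))
            self.inv_x0[i] = 1.0 / mat.radiation_length
            self.k_str[i] = BOHR_COEFF * mat.z_over_a
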