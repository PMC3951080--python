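"""Stopping power, range, scattering, straggling and HU conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spedose.materials import (
    BUILTIN_MATERIALS,
    HUConversionTable,
    Material,
    collision_stopping_power,
    csda_range,
    default_hu_table,
    hu_to_material,
    scattering_sigma,
    straggling_sigma,
)


class TestStoppingPower:
    def test_monotone_decrease_over_spe_band(self, water):
        assert (collision_stopping_power(water, "proton", 80.0)
                < collision_stopping_power(water, "proton", 20.0))

    def test_density_scaling_exact(self, water):
        doubled = water.with_density(2.0)
        s1 = collision_stopping_power(water, "proton", 50.0)
        s2 = collision_stopping_power(doubled, "proton", 50.0)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-12)

    def test_vacuum_limit(self, water):
        thin = water.with_density(1e-9)
        assert collision_stopping_power(thin, "proton", 50.0) < 1e-7

    @pytest.mark.parametrize("particle,energy,nist", [
        # NIST PSTAR/ESTAR reference values for liquid water, MeV cm^2/g
        ("proton", 50.0, 12.45),
        ("proton", 20.0, 26.49),
        ("electron", 1.0, 1.849),
    ])
    def test_against_published_water_values(self, water, particle, energy, nist):
        # Bethe / Berger-Seltzer without corrections: expect a few percent
        assert collision_stopping_power(water, particle, energy) == \
            pytest.approx(nist, rel=0.03)

    def test_rejects_energy_below_validity_floor(self, water):
        with pytest.raises(ValueError):
            collision_stopping_power(water, "proton", 0.5)
        with pytest.raises(ValueError):
            collision_stopping_power(water, "electron", -1.0)


class TestCSDARange:
    def test_zero_energy_zero_range(self, water):
        assert csda_range(water, "proton", 0.0) == 0.0

    def test_monotone_in_energy(self, water):
        energies = np.linspace(5, 120, 40)
        ranges = [csda_range(water, "proton", e) for e in energies]
        assert np.all(np.diff(ranges) > 0)

    def test_bragg_kleeman_fit_within_3pct(self, water):
        """R = alpha*E^p fitted to the table itself reproduces it to 3%."""
        energies = np.arange(20.0, 81.0, 2.0)
        r = np.array([csda_range(water, "proton", e) for e in energies])
        p, loga = np.polyfit(np.log(energies), np.log(r), 1)
        fit = np.exp(loga) * energies ** p
        assert np.max(np.abs(fit - r) / r) < 0.03
        assert 1.6 < p < 1.9  # the canonical Bragg-Kleeman exponent ~1.75

    def test_published_water_proton_ranges(self, water):
        # NIST PSTAR CSDA ranges: 20 MeV -> 0.4260 cm, 80 MeV -> 5.184 cm
        assert csda_range(water, "proton", 20.0) == pytest.approx(0.4260, rel=0.02)
        assert csda_range(water, "proton", 80.0) == pytest.approx(5.184, rel=0.02)


class TestScatteringSigma:
    def test_small_step_limit(self, water):
        assert scattering_sigma(water, "proton", 50.0, 1e-8) < 1e-4

    def test_sqrt_step_scaling_with_log_tolerance(self, water):
        s1 = scattering_sigma(water, "proton", 50.0, 0.05)
        s4 = scattering_sigma(water, "proton", 50.0, 0.20)
        assert s4 / s1 == pytest.approx(2.0, rel=0.15)

    def test_decreases_with_energy(self, water):
        assert (scattering_sigma(water, "proton", 80.0, 0.1)
                < scattering_sigma(water, "proton", 20.0, 0.1))

    def test_rejects_nonpositive_step(self, water):
        with pytest.raises(ValueError):
            scattering_sigma(water, "proton", 50.0, 0.0)


class TestStragglingSigma:
    def test_sqrt_step_scaling(self, water):
        s1 = straggling_sigma(water, "proton", 50.0, 0.05)
        s4 = straggling_sigma(water, "proton", 50.0, 0.20)
        assert s4 == pytest.approx(2.0 * s1, rel=1e-9)

    def test_small_against_mean_loss_50mev_1mm(self, water):
        sigma = straggling_sigma(water, "proton", 50.0, 0.1)
        mean_loss = collision_stopping_power(water, "proton", 50.0) * 0.1
        assert sigma < mean_loss


class TestHUConversion:
    def test_hounsfield_anchors(self):
        table = default_hu_table()
        idx, rho = hu_to_material(0.0, table)
        assert table.materials[idx] == "soft_tissue"
        assert rho == pytest.approx(1.00, abs=1e-9)
        idx, rho = hu_to_material(-1000.0, table)
        assert table.materials[idx] == "air"

    def test_boundary_goes_to_lower_bin(self):
        table = default_hu_table()
        idx, _ = hu_to_material(-950.0, table)
        assert table.materials[idx] == "air"
        idx, _ = hu_to_material(120.0, table)
        assert table.materials[idx] == "soft_tissue"

    def test_out_of_span_clamped(self):
        table = default_hu_table()
        idx_lo, _ = hu_to_material(-5000.0, table)
        idx_hi, rho_hi = hu_to_material(9000.0, table)
        assert table.materials[idx_lo] == "air"
        assert table.materials[idx_hi] == "bone"
        assert rho_hi > 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            HUConversionTable(entries=[])

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError):
            HUConversionTable(entries=[
                (-1000.0, -500.0, "air", (1.2e-3, 0.0)),
                (-400.0, 0.0, "soft_tissue", (1.0, 1e-3)),
            ])

    @given(st.lists(st.floats(-1000, 2000), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_density_monotone_over_hu_ramp(self, hus):
        table = default_hu_table()
        hus = sorted(hus)
        rhos = [hu_to_material(h, table)[1] for h in hus]
        assert np.all(np.diff(rhos) >= -1e-12)


class TestMaterialInvariants:
    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Material("bad", {"H": 0.5, "O": 0.4}, 1.0)

    def test_builtin_compositions_valid(self):
        for name, mat in BUILTIN_MATERIALS.items():
            assert sum(mat.composition.values()) == pytest.approx(1.0, abs=1e-6)
            assert mat.density > 0
            assert mat.mean_excitation_energy > 0
            assert mat.radiation_length > 0

    def test_water_radiation_length(self, water):
        assert water.radiation_length == pytest.approx(36.08, rel=0.02)

    def test_solid_water_is_the_reference_mixture(self):
        sw = BUILTIN_MATERIALS["solid_water"]
        assert sw.composition["C"] == pytest.approx(0.6717)
        assert sw.density == pytest.approx(1.04)
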