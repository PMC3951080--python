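"""Condensed-history stepping, scoring, batches."""

import numpy as np
import pytest

from spedose.analysis import depth_profile
from spedose.beams import BeamSpec, ParticleState
from spedose.materials import csda_range, get_material
from spedose.phantoms import make_slab_phantom
from spedose.transport import (
    DoseGrid,
    TransportConfig,
    combine_batches,
    run_transport,
    step_particle,
)
from spedose.unfold import Spectrum


def _mono_beam(energy, halfwidth=1.0):
    return BeamSpec(particle="proton", parallel=True,
                    spectrum=Spectrum.monoenergetic(energy),
                    field_halfwidth=halfwidth)


class TestRunTransport:
    def test_zero_histories_zero_dose(self, small_water_grid):
        cfg = TransportConfig(n_histories=0)
        dose = run_transport(small_water_grid, _mono_beam(30.0), cfg, seed=0)
        assert not dose.dose_mean.any()

    def test_same_seed_bitwise_identical(self, small_water_grid):
        cfg = TransportConfig(n_histories=500, base_seed=3)
        beam = _mono_beam(30.0)
        d1 = run_transport(small_water_grid, beam, cfg, seed=3)
        d2 = run_transport(small_water_grid, beam, cfg, seed=3)
        np.testing.assert_array_equal(d1.dose_mean, d2.dose_mean)

    def test_energy_conservation_all_stopping(self, proton_dose_30mev):
        """With every primary stopping inside, deposits equal initial energy.

        The residual below the cutoff is deposited locally, so the ledger
        closes exactly (radiative and nuclear channels are zero for protons).
        """
        _, stats, _, _ = proton_dose_30mev
        assert stats["escaped"] == 0.0
        assert stats["deposited"] == pytest.approx(stats["initial"], rel=1e-9)

    def test_bragg_peak_position_vs_range_oracle(self, proton_dose_30mev, water):
        """Peak slab within one voxel of the CSDA range prediction."""
        dose, _, _, _ = proton_dose_30mev
        prof = depth_profile(dose, axis="+x", radius=0.5)
        peak = prof.depth[np.argmax(prof.dose)]
        dx = dose.grid.spacing[0]
        assert abs(peak - csda_range(water, "proton", 30.0)) <= dx

    def test_bragg_curve_shape(self, proton_dose_30mev):
        """Entrance dose below peak; distal tail beyond peak+3mm below 1%."""
        dose, _, _, _ = proton_dose_30mev
        prof = depth_profile(dose, axis="+x", radius=0.5)
        k = int(np.argmax(prof.dose))
        assert prof.dose[0] < 0.5 * prof.dose[k]
        tail = prof.dose[prof.depth > prof.depth[k] + 0.3]
        assert tail.max() < 0.01 * prof.dose[k]

    def test_air_grid_negligible_deposit(self):
        air_grid = make_slab_phantom("air", (4.0, 3.0, 3.0), (0.1, 0.15, 0.15))
        water_grid = make_slab_phantom("water", (4.0, 3.0, 3.0), (0.1, 0.15, 0.15))
        cfg = TransportConfig(n_histories=200, base_seed=1)
        beam = _mono_beam(30.0)
        _, s_air = run_transport(air_grid, beam, cfg, seed=1, return_stats=True)
        _, s_wat = run_transport(water_grid, beam, cfg, seed=1, return_stats=True)
        assert s_air["deposited"] < 1e-2 * s_wat["deposited"]

    def test_nuclear_attenuation_removes_fluence(self, small_water_grid):
        beam = _mono_beam(50.0)
        base = TransportConfig(n_histories=500, base_seed=5)
        attn = TransportConfig(n_histories=500, base_seed=5,
                               nuclear_attenuation_per_cm_water=0.05)
        _, s0 = run_transport(small_water_grid, beam, base, seed=5,
                              return_stats=True)
        _, s1 = run_transport(small_water_grid, beam, attn, seed=5,
                              return_stats=True)
        assert s1["nuclear"] > 0
        assert s1["deposited"] < s0["deposited"]


class TestCombineBatches:
    def _dose(self, arr, grid, hist=10):
        return DoseGrid(arr, np.zeros_like(arr), hist, grid)

    def test_identical_batches(self, small_water_grid):
        arr = np.full(small_water_grid.dims, 2.5)
        out = combine_batches([self._dose(arr, small_water_grid)] * 3)
        np.testing.assert_allclose(out.dose_mean, arr)
        np.testing.assert_allclose(out.dose_sem, 0.0)
        assert out.histories == 30

    def test_two_point_formula(self, small_water_grid):
        d = np.random.default_rng(0).random(small_water_grid.dims)
        out = combine_batches([self._dose(d, small_water_grid),
                               self._dose(3 * d, small_water_grid)])
        np.testing.assert_allclose(out.dose_mean, 2 * d)
        # population-std convention: sem({D, 3D}) = D / sqrt(2)
        np.testing.assert_allclose(out.dose_sem, d / np.sqrt(2), rtol=1e-12)

    def test_sem_scales_with_batch_count(self, small_water_grid):
        """Regrouping 10 batches into 5 pairs scales sem by ~1/sqrt(2)."""
        rng = np.random.default_rng(1)
        arrs = [1.0 + 0.1 * rng.standard_normal(small_water_grid.dims)
                for _ in range(10)]
        ten = combine_batches([self._dose(a, small_water_grid) for a in arrs])
        pairs = [self._dose((arrs[2 * i] + arrs[2 * i + 1]) / 2, small_water_grid)
                 for i in range(5)]
        five = combine_batches(pairs)
        ratio = ten.dose_sem.mean() / five.dose_sem.mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_single_batch_rejected(self, small_water_grid):
        with pytest.raises(ValueError):
            combine_batches([self._dose(np.ones(small_water_grid.dims),
                                        small_water_grid)])

    def test_dim_mismatch_rejected(self, small_water_grid):
        other = make_slab_phantom("water", (2.0, 2.0, 2.0), 0.5)
        with pytest.raises(ValueError):
            combine_batches([
                self._dose(np.ones(small_water_grid.dims), small_water_grid),
                self._dose(np.ones(other.dims), other)])


class TestStepParticle:
    def test_track_conserves_energy_without_sampling(self, small_water_grid):
        cfg = TransportConfig(n_histories=1, straggling=False, scattering=False)
        rng = np.random.default_rng(0)
        state = ParticleState(position=np.array([-1.0, 0.0, 0.0]),
                              direction=np.array([1.0, 0.0, 0.0]),
                              energy=30.0, kind="proton")
        total = 0.0
        for _ in range(100_000):
            state, deposits = step_particle(state, small_water_grid, cfg, rng)
            total += sum(d for _, d in deposits)
            if state.energy <= 1e-20:
                break
        assert total == pytest.approx(30.0, rel=1e-6)

    def test_stopping_depth_matches_range_oracle(self, water):
        # 50 MeV needs ~2.2 cm of water; use a deep enough column
        grid = make_slab_phantom("water", (4.0, 1.0, 1.0), (0.05, 0.25, 0.25))
        cfg = TransportConfig(n_histories=1, straggling=False, scattering=False)
        rng = np.random.default_rng(0)
        state = ParticleState(position=np.array([-3.0, 0.0, 0.0]),
                              direction=np.array([1.0, 0.0, 0.0]),
                              energy=50.0, kind="proton")
        for _ in range(100_000):
            state, _ = step_particle(state, grid, cfg, rng)
            if state.energy <= 1e-20:
                break
        depth = state.position[0] - grid.extent[0][0]
        assert depth == pytest.approx(csda_range(water, "proton", 50.0), rel=0.02)

    def test_vacuum_flight_outside_grid(self, small_water_grid):
        cfg = TransportConfig(n_histories=1)
        rng = np.random.default_rng(0)
        state = ParticleState(position=np.array([-5.0, 0.0, 0.0]),
                              direction=np.array([1.0, 0.0, 0.0]),
                              energy=30.0, kind="proton")
        state2, deposits = step_particle(state, small_water_grid, cfg, rng)
        assert deposits == []
        assert state2.energy == 30.0
        assert state2.position[0] > small_water_grid.extent[0][0] - 1e-6
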