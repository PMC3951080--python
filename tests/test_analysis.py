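"""Depth profiles, normalization, beam mixing, angle weighting, DVHs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spedose.analysis import (
    DepthProfile,
    combine_angles,
    compute_dvh,
    depth_profile,
    mix_beams,
    normalize_at_dmax,
    profile_deviation,
    shift_profile,
)
from spedose.geometry import StructureMask
from spedose.phantoms import make_slab_phantom
from spedose.transport import DoseGrid


@pytest.fixture()
def grid():
    return make_slab_phantom("water", (2.0, 2.0, 2.0), 0.1)


def _dose(grid, arr, sem=None):
    sem = np.zeros_like(arr) if sem is None else sem
    return DoseGrid(arr, sem, 100, grid)


class TestDepthProfile:
    def test_uniform_dose_flat_profile(self, grid):
        d = _dose(grid, np.full(grid.dims, 3.0))
        prof = depth_profile(d, axis="+x", radius=0.5)
        np.testing.assert_allclose(prof.dose, 3.0)

    def test_dose_outside_cylinder_invisible(self, grid):
        arr = np.zeros(grid.dims)
        arr[:, 0, :] = 7.0  # lateral edge, ~0.95 cm off axis
        prof = depth_profile(_dose(grid, arr), axis="+x", radius=0.5)
        np.testing.assert_allclose(prof.dose, 0.0)

    def test_linear_ramp_reproduced(self, grid):
        x = np.arange(grid.dims[0])
        arr = np.broadcast_to((1.0 + x)[:, None, None], grid.dims).copy()
        prof = depth_profile(_dose(grid, arr), axis="+x")
        np.testing.assert_allclose(np.diff(prof.dose), 1.0, atol=1e-12)

    def test_tiny_radius_warns_and_uses_column(self, grid):
        d = _dose(grid, np.full(grid.dims, 1.0))
        with pytest.warns(UserWarning, match="radius"):
            prof = depth_profile(d, axis="+x", radius=0.01)
        np.testing.assert_allclose(prof.dose, 1.0)

    def test_negative_axis_reverses_depth(self, grid):
        x = np.arange(grid.dims[0])
        arr = np.broadcast_to((1.0 + x)[:, None, None], grid.dims).copy()
        p_fwd = depth_profile(_dose(grid, arr), axis="+x")
        p_bwd = depth_profile(_dose(grid, arr), axis="-x")
        np.testing.assert_allclose(p_bwd.dose, p_fwd.dose[::-1])


class TestNormalizeAtDmax:
    def test_idempotent(self):
        p = DepthProfile(np.linspace(0.1, 5, 40),
                         np.exp(-((np.linspace(0.1, 5, 40) - 2) ** 2)))
        n1 = normalize_at_dmax(p)
        n2 = normalize_at_dmax(n1)
        np.testing.assert_allclose(n1.dose, n2.dose)
        assert n1.dose.max() == pytest.approx(1.0)

    def test_scale_invariance(self):
        depth = np.linspace(0.1, 5, 40)
        dose = np.exp(-((depth - 2) ** 2))
        n1 = normalize_at_dmax(DepthProfile(depth, dose))
        n2 = normalize_at_dmax(DepthProfile(depth, 37.5 * dose))
        np.testing.assert_allclose(n1.dose, n2.dose)
        assert n1.dmax_depth == n2.dmax_depth

    def test_parabolic_vertex_between_samples(self):
        depth = np.array([1.0, 2.0, 3.0])
        # parabola peaking at 2.25: y = 1 - (x - 2.25)^2 / 4
        dose = 1.0 - (depth - 2.25) ** 2 / 4.0
        n = normalize_at_dmax(DepthProfile(depth, dose))
        assert n.dmax_depth == pytest.approx(2.25, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_at_dmax(DepthProfile(np.array([1.0, 2.0]),
                                           np.array([0.0, 0.0])))


class TestMixBeams:
    def test_single_component(self, grid):
        arr = np.random.default_rng(0).random(grid.dims)
        out = mix_beams([_dose(grid, arr), _dose(grid, 2 * arr)],
                        dmax_doses=[arr.max(), 2 * arr.max()],
                        fractions=[1.0, 0.0], prescription=5.0)
        np.testing.assert_allclose(out.dose_mean, 5.0 * arr / arr.max())

    def test_identical_components_half_half(self, grid):
        arr = np.random.default_rng(1).random(grid.dims)
        full = mix_beams([_dose(grid, arr)], [arr.max()], [1.0])
        half = mix_beams([_dose(grid, arr), _dose(grid, arr)],
                         [arr.max(), arr.max()], [0.5, 0.5])
        np.testing.assert_allclose(half.dose_mean, full.dose_mean, rtol=1e-12)

    def test_80_20_mixture_equals_weighted_normalized_profiles(self, grid):
        """The 6+12 MeV rule: combined = 0.8*P_low + 0.2*P_high exactly."""
        rng = np.random.default_rng(2)
        a6, a12 = rng.random(grid.dims), rng.random(grid.dims)
        d6, d12 = _dose(grid, a6), _dose(grid, a12)
        p6 = normalize_at_dmax(depth_profile(d6))
        p12 = normalize_at_dmax(depth_profile(d12))
        dm6 = depth_profile(d6).dose.max()
        dm12 = depth_profile(d12).dose.max()
        mixed = mix_beams([d6, d12], [dm6, dm12], [0.8, 0.2])
        pm = depth_profile(mixed)
        np.testing.assert_allclose(pm.dose, 0.8 * p6.dose + 0.2 * p12.dose,
                                   rtol=1e-12)

    def test_zero_dmax_rejected(self, grid):
        with pytest.raises(ValueError):
            mix_beams([_dose(grid, np.ones(grid.dims))], [0.0], [1.0])

    def test_linearity_to_float_tolerance(self, grid):
        rng = np.random.default_rng(3)
        arrs = [rng.random(grid.dims) for _ in range(2)]
        ds = [_dose(grid, a) for a in arrs]
        dmx = [a.max() for a in arrs]
        out = mix_beams(ds, dmx, [0.8, 0.2], prescription=2.0)
        expect = 2.0 * (0.8 * arrs[0] / dmx[0] + 0.2 * arrs[1] / dmx[1])
        assert np.abs(out.dose_mean - expect).max() < 1e-12


class TestCombineAngles:
    def test_single_angle_identity(self, grid):
        arr = np.random.default_rng(0).random(grid.dims)
        out = combine_angles({0: _dose(grid, arr)}, {0: 1.0})
        np.testing.assert_array_equal(out.dose_mean, arr)

    def test_lats_appa_70_30_identity(self, grid):
        rng = np.random.default_rng(1)
        d = {a: _dose(grid, rng.random(grid.dims)) for a in (0, 90, 180, 270)}
        out = combine_angles(d, {0: 0.35, 180: 0.35, 90: 0.15, 270: 0.15})
        lats = 0.5 * (d[0].dose_mean + d[180].dose_mean)
        appa = 0.5 * (d[90].dose_mean + d[270].dose_mean)
        np.testing.assert_allclose(out.dose_mean, 0.7 * lats + 0.3 * appa,
                                   atol=1e-12)

    def test_missing_angle_rejected(self, grid):
        with pytest.raises(ValueError, match="missing"):
            combine_angles({0: _dose(grid, np.ones(grid.dims))},
                           {0: 0.5, 180: 0.5})

    def test_weights_must_sum_to_one(self, grid):
        with pytest.raises(ValueError):
            combine_angles({0: _dose(grid, np.ones(grid.dims))}, {0: 0.7})


class TestComputeDVH:
    def test_uniform_dose_step_function(self, grid):
        mask = StructureMask("m", np.ones(grid.dims, dtype=bool))
        dvh = compute_dvh(_dose(grid, np.full(grid.dims, 4.0)), mask,
                          bin_width=0.5)
        below = dvh.dose_edges <= 4.0
        np.testing.assert_allclose(dvh.volume_fraction[below], 1.0)
        np.testing.assert_allclose(dvh.volume_fraction[~below], 0.0)

    def test_half_half_plateau(self, grid):
        arr = np.zeros(grid.dims)
        arr[:10] = 6.0
        mask = StructureMask("m", np.ones(grid.dims, dtype=bool))
        dvh = compute_dvh(_dose(grid, arr), mask, bin_width=0.5)
        mid = (dvh.dose_edges > 0) & (dvh.dose_edges <= 6.0)
        np.testing.assert_allclose(dvh.volume_fraction[mid], 0.5)

    def test_uniform_random_matches_analytic_cdf(self):
        grid = make_slab_phantom("water", (5.0, 5.0, 4.0), 0.1)
        rng = np.random.default_rng(0)
        big_d = 10.0
        arr = rng.uniform(0, big_d, size=grid.dims)
        mask = StructureMask("m", np.ones(grid.dims, dtype=bool))
        dvh = compute_dvh(DoseGrid(arr, np.zeros_like(arr), 1, grid), mask)
        expect = 1.0 - np.clip(dvh.dose_edges / big_d, 0, 1)
        assert np.abs(dvh.volume_fraction - expect).max() < 0.01

    def test_mean_dose_from_curve(self, grid):
        rng = np.random.default_rng(1)
        arr = rng.random(grid.dims) * 3
        mask = StructureMask("m", rng.random(grid.dims) > 0.4)
        bw = arr.max() / 500
        dvh = compute_dvh(_dose(grid, arr), mask, bin_width=bw)
        assert dvh.mean_dose() == pytest.approx(arr[mask.mask].mean(), abs=bw / 2)

    def test_empty_mask_rejected(self, grid):
        with pytest.raises(ValueError):
            compute_dvh(_dose(grid, np.ones(grid.dims)),
                        StructureMask("m", np.zeros(grid.dims, dtype=bool)))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_monotone_with_endpoints_on_random_fields(self, seed):
        grid = make_slab_phantom("water", (1.0, 1.0, 1.0), 0.2)
        rng = np.random.default_rng(seed)
        arr = np.abs(rng.standard_normal(grid.dims)) ** 2
        mask = StructureMask("m", np.ones(grid.dims, dtype=bool))
        dvh = compute_dvh(DoseGrid(arr, np.zeros_like(arr), 1, grid), mask)
        assert dvh.volume_fraction[0] == 1.0
        assert np.all(np.diff(dvh.volume_fraction) <= 1e-12)
        assert dvh.volume_fraction[-1] == 0.0


class TestProfileDeviation:
    def test_identical_profiles_zero(self):
        depth = np.linspace(0.1, 4, 50)
        dose = np.exp(-((depth - 1.5) ** 2))
        p = DepthProfile(depth, dose)
        assert profile_deviation([p, p]) == 0.0

    def test_known_pair_value(self):
        """Values (1.00, 1.02) at the evaluation point -> 0.0196."""
        depth = np.linspace(0.1, 4, 50)
        base = 1.0 - ((depth - 2.0) / 4) ** 2
        p1 = DepthProfile(depth, base)
        p2 = DepthProfile(depth, 1.02 * base)
        assert profile_deviation([p1, p2]) == pytest.approx(1 - 1 / 1.02,
                                                            abs=1e-6)

    def test_scaled_copies_after_normalization(self):
        depth = np.linspace(0.1, 4, 50)
        dose = np.exp(-((depth - 1.5) ** 2))
        p1 = normalize_at_dmax(DepthProfile(depth, dose))
        p2 = normalize_at_dmax(DepthProfile(depth, 5.0 * dose))
        assert profile_deviation([p1, p2]) < 1e-12

    def test_disjoint_supports_rejected(self):
        p1 = DepthProfile(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        p2 = DepthProfile(np.array([2.0, 3.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="disjoint"):
            profile_deviation([p1, p2])

    def test_fixed_depth_evaluation(self):
        depth = np.linspace(0.0, 4.0, 41)
        p1 = DepthProfile(depth, np.full_like(depth, 1.0))
        p2 = DepthProfile(depth, np.full_like(depth, 0.9))
        assert profile_deviation([p1, p2], at=2.0) == pytest.approx(0.1)


class TestShiftProfile:
    def test_zero_offset_identity(self):
        p = DepthProfile(np.array([1.0, 2.0]), np.array([0.5, 0.7]))
        s = shift_profile(p, 0.0)
        np.testing.assert_array_equal(s.depth, p.depth)

    def test_roundtrip(self):
        p = DepthProfile(np.array([1.0, 2.0]), np.array([0.5, 0.7]))
        s = shift_profile(shift_profile(p, 0.5), -0.5)
        np.testing.assert_allclose(s.depth, p.depth)

    def test_dmax_shifts_with_offset(self):
        depth = np.linspace(0.1, 4, 50)
        p = normalize_at_dmax(DepthProfile(depth, np.exp(-((depth - 1.5) ** 2))))
        s = shift_profile(p, 0.5)  # the 5 mm enclosure-wall shift
        assert s.dmax_depth == pytest.approx(p.dmax_depth + 0.5)
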