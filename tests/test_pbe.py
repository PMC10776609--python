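"""Size grid, minmod reconstruction, growth/dissolution fluxes, CSD stats."""

import numpy as np
import pytest

from jetcryst import pbe
from jetcryst import verification as ver


class TestGrid:
    @pytest.mark.parametrize("n,dr", [(30, 2e-6), (60, 1e-6), (15, 4e-6)])
    def test_uniform_width(self, n, dr):
        grid = pbe.make_grid(0.0, 60e-6, n)
        assert grid.n == n
        assert grid.dr == pytest.approx(dr, rel=1e-14)
        assert np.all(np.diff(grid.r_faces) > 0)

    def test_centers_are_midpoints(self, default_grid):
        assert default_grid.r_centers[0] == pytest.approx(1e-6)
        assert default_grid.r_centers[-1] == pytest.approx(59e-6)

    @pytest.mark.parametrize("args", [(0.0, 0.0, 30), (1e-5, 5e-6, 30),
                                      (0.0, 60e-6, 2), (-1e-6, 60e-6, 30)])
    def test_invalid_grids_rejected(self, args):
        with pytest.raises(ValueError):
            pbe.make_grid(*args)

    def test_nonuniform_faces_rejected(self):
        faces = np.array([0.0, 1e-6, 3e-6, 4e-6, 5e-6])
        with pytest.raises(ValueError, match="uniform"):
            pbe.SizeGrid(r_faces=faces)


class TestMinmod:
    @pytest.mark.parametrize("candidates,expected", [
        ((2.0, 3.0, 1.0), 1.0),      # all positive -> min
        ((-2.0, 1.0, 3.0), 0.0),     # mixed signs -> 0
        ((-2.0, -1.0, -3.0), -1.0),  # all negative -> max
        ((0.0, 1.0, 2.0), 0.0),      # zero candidate -> 0
    ])
    def test_scalar_cases(self, candidates, expected):
        assert pbe.minmod(*candidates) == expected

    def test_elementwise_on_arrays(self):
        a = np.array([1.0, -1.0, 2.0])
        b = np.array([2.0, -3.0, -2.0])
        np.testing.assert_allclose(pbe.minmod(a, b), [1.0, -1.0, 0.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pbe.minmod()


class TestLimitedSlopes:
    def test_linear_profile_reproduced_exactly(self, default_grid):
        a = 3e18
        f = a * default_grid.r_centers + 1e12
        slopes = pbe.limited_slopes(f, default_grid)
        np.testing.assert_allclose(slopes[1:-1], a, rtol=1e-12)

    def test_local_maximum_clipped_to_zero(self, default_grid):
        f = np.ones(default_grid.n)
        f[10] = 3.0
        f[11] = 2.0
        slopes = pbe.limited_slopes(f, default_grid)
        assert slopes[10] == 0.0

    def test_uniform_field_has_zero_slopes(self, default_grid):
        slopes = pbe.limited_slopes(np.full(default_grid.n, 7.0), default_grid)
        assert np.all(slopes == 0.0)

    def test_theta_out_of_range_rejected(self, default_grid):
        with pytest.raises(ValueError):
            pbe.limited_slopes(np.ones(default_grid.n), default_grid, theta=2.5)


class TestGrowthFlux:
    def test_uniform_field_constant_growth_is_stationary_in_the_interior(
            self, default_grid):
        f = np.full(default_grid.n, 5e14)
        dfdt = pbe.growth_flux_divergence(f, 1e-6, default_grid, mode="growth",
                                          outer_bc="outflow")
        np.testing.assert_allclose(dfdt[1:-1], 0.0, atol=1e-20)

    def test_number_conserved_until_mass_reaches_outer_boundary(self, default_grid):
        f0 = np.zeros(default_grid.n)
        f0[5] = 1e15
        f1 = pbe.advect(f0, 1e-6, 10.0, default_grid)  # shift by 5 classes
        total0 = f0.sum() * default_grid.dr
        total1 = f1.sum() * default_grid.dr
        assert total1 == pytest.approx(total0, rel=1e-10)

    def test_gaussian_pulse_follows_analytic_translation(self):
        grid = pbe.make_grid(0.0, 60e-6, 60)
        prof = ver.gaussian_profile(20e-6, 4e-6, 1e15)
        err = ver.advection_l1_error(prof, 1e-6, 10.0, grid)
        assert err < 0.05

    def test_negative_speed_rejected(self, default_grid):
        with pytest.raises(ValueError):
            pbe.growth_flux_divergence(np.ones(default_grid.n), -1e-6,
                                       default_grid)

    def test_zero_flux_outer_boundary_retains_number(self, default_grid):
        f0 = np.zeros(default_grid.n)
        f0[-5] = 1e15
        f1 = pbe.advect(f0, 1e-6, 30.0, default_grid, outer_bc="zero_flux")
        assert f1.sum() * default_grid.dr == pytest.approx(
            f0.sum() * default_grid.dr, rel=1e-10)

    def test_dissolution_is_adjoint_advection(self):
        # shifting up then dissolving back returns the pulse to its origin
        grid = pbe.make_grid(0.0, 60e-6, 60)
        f0 = ver.class_averages(ver.gaussian_profile(20e-6, 4e-6, 1e15), grid)
        fg = pbe.advect(f0, 1e-6, 10.0, grid, mode="growth", outer_bc="outflow")
        fb = pbe.advect(fg, 1e-6, 10.0, grid, mode="dissolution")
        one_way = ver.advection_l1_error(
            ver.gaussian_profile(20e-6, 4e-6, 1e15), 1e-6, 10.0, grid)
        round_trip = np.abs(fb - f0).sum() / np.abs(f0).sum()
        assert round_trip <= 2.0 * one_way


class TestNucleationSource:
    def test_deposits_entirely_into_first_class(self, default_grid):
        src = pbe.nucleation_source(1e12, default_grid)
        assert src[0] == pytest.approx(5e17)
        assert np.all(src[1:] == 0.0)
        # the delta-source integral is conserved by the discretization
        assert src.sum() * default_grid.dr == pytest.approx(1e12)

    def test_linearity(self, default_grid):
        s = pbe.nucleation_source(3e11, default_grid) \
            + pbe.nucleation_source(7e11, default_grid)
        np.testing.assert_allclose(s, pbe.nucleation_source(1e12, default_grid))

    def test_zero_rate_gives_zero_field(self, default_grid):
        assert np.all(pbe.nucleation_source(0.0, default_grid) == 0.0)


class TestNumberToMass:
    def test_against_independent_quadrature(self):
        # oracle: trapezoidal integral of rho_c k_v r^3 f over each class
        grid = pbe.make_grid(2e-6, 10e-6, 4)
        f = np.array([1e12, 5e11, 2e11, 0.0])
        rho_c, k_v = 1273.0, np.pi / 6.0
        f_w = pbe.number_to_mass(f, grid, rho_c, k_v)
        for j in range(grid.n):
            r = np.linspace(grid.r_faces[j], grid.r_faces[j + 1], 20001)
            ref = rho_c * k_v * f[j] * np.trapezoid(r**3, r)
            assert f_w[j] == pytest.approx(ref, rel=1e-7)

    def test_single_class_frozen_value(self):
        # faces 2-4 um, f = 1e12 #/m^4: exact fourth-power integral
        grid = pbe.make_grid(2e-6, 4e-6, 3)
        f = np.array([3e12, 0.0, 0.0])  # first sub-class 2-2.667 um
        f_w = pbe.number_to_mass(f, grid, 1273.0, np.pi / 6.0)
        rho_kv = 1273.0 * np.pi / 6.0
        expected = rho_kv * 3e12 * (grid.r_faces[1]**4 - grid.r_faces[0]**4) / 4
        assert f_w[0] == pytest.approx(expected, rel=1e-14)

    def test_linearity_in_f(self, default_grid):
        f = np.linspace(0, 1e13, default_grid.n)
        one = pbe.number_to_mass(f, default_grid, 1273.0, 0.5)
        two = pbe.number_to_mass(2 * f, default_grid, 1273.0, 0.5)
        np.testing.assert_allclose(two, 2 * one)


class TestCSDSummary:
    def test_single_populated_class(self, default_grid):
        f = np.zeros(default_grid.n)
        f[5] = 1e15  # class centered at 11 um
        stats = pbe.csd_summary(f, default_grid)
        assert stats.number_mean == pytest.approx(11e-6)
        assert stats.mass_mean == pytest.approx(11e-6)
        assert stats.number_std == pytest.approx(0.0, abs=1e-12)
        assert stats.mass_std == pytest.approx(0.0, abs=1e-12)

    def test_msmpr_exponential_moments(self):
        # number mean -> G tau, mass-weighted mean -> 4 G tau
        grid = pbe.make_grid(0.0, 150e-6, 600)
        f = ver.msmpr_analytic(B=1e12, G=1e-6, tau=10.0, grid=grid)
        stats = pbe.csd_summary(f, grid)
        assert stats.number_mean == pytest.approx(10e-6, rel=0.02)
        assert stats.mass_mean == pytest.approx(40e-6, rel=0.02)
        assert stats.total_number == pytest.approx(1e13, rel=0.01)  # B tau

    def test_symmetric_distribution_mean_at_center(self, default_grid):
        f = ver.class_averages(ver.gaussian_profile(30e-6, 5e-6, 1e15),
                               default_grid)
        stats = pbe.csd_summary(f, default_grid)
        assert stats.number_mean == pytest.approx(30e-6, rel=1e-3)

    def test_empty_field_flagged(self, default_grid):
        stats = pbe.csd_summary(np.zeros(default_grid.n), default_grid)
        assert stats.empty
        assert np.isnan(stats.number_mean)


class TestSchemeProperties:
    def test_tvd_no_new_extrema_no_negatives(self, default_grid, rng):
        peak_grow = 0
        for _ in range(50):
            f0 = rng.random(default_grid.n) * 10 ** rng.integers(0, 12)
            f1 = pbe.advect(f0, 1e-6, 7.0, default_grid, outer_bc="outflow")
            assert f1.min() >= -1e-12 * f0.max()
            if f1.max() > f0.max() * (1 + 1e-12):
                peak_grow += 1
        assert peak_grow == 0

    def test_smooth_convergence_order(self):
        order, errs = ver.smooth_convergence_order()
        assert order >= 1.8
        assert errs[1] / errs[2] >= 3.4  # 2 um -> 1 um refinement

    def test_first_order_control_scheme(self):
        prof = ver.gaussian_profile(**ver.CONVERGENCE_PROFILE)
        order, _ = ver.advection_convergence(
            prof, G=1e-6, t_end=30.0, r_max=ver.CONVERGENCE_SPAN,
            integrator=ver.upwind_advect)
        assert order == pytest.approx(1.0, abs=0.15)

    def test_discontinuous_profile_order(self):
        # contact discontinuities under TVD limiters converge at the
        # theoretical O(h^(2/3)) rate, well below the smooth-data order
        step = ver.step_profile(40e-6, 80e-6, 1e15)
        order, _ = ver.advection_convergence(
            step, G=1e-6, t_end=20.0, r_max=ver.CONVERGENCE_SPAN)
        assert 2.0 / 3.0 - 0.1 <= order < 1.2
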