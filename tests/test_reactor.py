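"""Compartment networks: construction, conservation, MSMPR limit, sweeps."""

import numpy as np
import pytest

from jetcryst import RunConfig, pbe
from jetcryst import reactor as rx
from jetcryst import verification as ver


def make_cfg(**overrides):
    return RunConfig.model_validate(overrides)


class TestBuildNetwork:
    def test_mixed_cell_flow_balance(self):
        cfg = make_cfg(template="mixed_cell")
        net = rx.build_network(cfg)
        assert net.nc == 1
        q_in = sum(i.Q for i in net.inlets)
        assert net.Q_outlet.sum() == pytest.approx(q_in, rel=1e-14)

    def test_anti_solvent_mass_flow_to_volumetric(self):
        cfg = make_cfg(inlets={"anti_solvent": {"mass_flow": 498.6e-6,
                                                "velocity": None}})
        net = rx.build_network(cfg)
        anti = next(i for i in net.inlets if i.name == "anti_solvent")
        assert anti.Q == pytest.approx(498.6e-6 / 997.1, rel=1e-12)

    def test_chain_has_equal_volume_compartments(self):
        cfg = make_cfg(template="pfr_chain", network={"n_chambers": 20})
        net = rx.build_network(cfg)
        assert net.nc == 20
        np.testing.assert_allclose(net.volumes, net.volumes[0])
        assert net.positions is not None

    def test_impinging_jet_topology(self):
        net = rx.build_network(make_cfg())
        assert net.nc == 5  # impingement + 4 chambers
        assert net.volumes[0] == pytest.approx(0.2 * net.volumes.sum())
        assert np.all(np.diff(net.eps_over_k) < 0)  # turbulence decays downstream

    def test_prescribed_turbulence_wrong_length_rejected(self):
        cfg = make_cfg(network={"turbulence": {
            "mode": "prescribed", "eps_over_k": [100.0, 50.0]}})
        with pytest.raises(ValueError, match="turbulence"):
            rx.build_network(cfg)

    def test_unbalanced_network_rejected(self, default_grid):
        with pytest.raises(ValueError, match="balanced"):
            rx.Network(
                volumes=np.array([1e-6]), Q=np.zeros((1, 1)),
                Q_outlet=np.array([1e-6]), inlets=[],
                eps_over_k=np.array([1.0]), D_t=np.array([0.0]),
                positions=None, grid=default_grid,
                phi1=np.zeros(3), phi2=np.zeros(3),
                constants=rx.kin.PhysicalConstants())


class TestClosedCellConservation:
    @pytest.fixture()
    def closed_result(self, default_grid):
        net = rx.closed_cell_network(default_grid, eps_over_k=50.0)
        y0 = net.initial_state("anti_solvent").reshape(1, -1).copy()
        y0[0, 0], y0[0, 1], y0[0, 2] = 0.5, 0.5, 0.0
        return rx.run(net, t_end=0.5, rtol=1e-10, atol=1e-12, y0=y0.ravel())

    def test_probability_normalisation_preserved(self, closed_result):
        rep = ver.conservation_audit(closed_result)
        assert rep["probability_norm_error"] < 1e-12

    def test_solute_plus_crystal_mass_closed(self, closed_result):
        rep = ver.conservation_audit(closed_result)
        assert rep["solute_plus_crystal_drift"] < 1e-8

    def test_solvent_means_invariant_under_micromixing(self, closed_result):
        rep = ver.conservation_audit(closed_result)
        assert rep["methanol_mean_drift"] < 1e-12
        assert rep["water_mean_drift"] < 1e-12

    def test_temperature_rises_with_exothermic_mixing(self, closed_result):
        net = closed_result.network
        assert closed_result.Y[0, net.i_T] > 298.15

    def test_no_heat_sources_keeps_temperature_constant(self, default_grid):
        net = rx.closed_cell_network(default_grid, eps_over_k=50.0,
                                     dH_mix=0.0, dH_crys=0.0)
        y0 = net.initial_state("anti_solvent").reshape(1, -1).copy()
        y0[0, 0], y0[0, 1], y0[0, 2] = 0.5, 0.5, 0.0
        res = rx.run(net, t_end=0.2, rtol=1e-10, atol=1e-12, y0=y0.ravel())
        assert res.Y[0, net.i_T] == pytest.approx(298.15, abs=1e-9)


class TestMSMPRLimit:
    def test_steady_csd_matches_analytic_exponential(self):
        # coarse fast check; the fine-grid version lives in the acceptance suite
        grid = pbe.make_grid(0.0, 60e-6, 30)
        net = ver.msmpr_network(grid, B=1e12, G=1e-6, tau=10.0)
        res = rx.run(net, steady_tol=1e-8, rtol=1e-8, max_residence_times=400)
        f_ref = ver.msmpr_analytic(1e12, 1e-6, 10.0, grid)
        l1 = np.abs(res.Y[0, net.f_slice] - f_ref).sum() / f_ref.sum()
        assert l1 < 0.05

    def test_total_number_approaches_B_tau(self):
        grid = pbe.make_grid(0.0, 60e-6, 30)
        net = ver.msmpr_network(grid, B=1e12, G=1e-6, tau=10.0)
        res = rx.run(net, steady_tol=1e-8, rtol=1e-8, max_residence_times=400)
        total = res.Y[0, net.f_slice].sum() * grid.dr
        assert total == pytest.approx(1e13, rel=0.01)


class TestRunBehavior:
    def test_saturated_feeds_produce_no_crystals(self):
        # premixed feed at exactly saturation: S = 1 everywhere, no kinetics
        cfg = make_cfg(
            template="mixed_cell",
            inlets={"solution": None, "anti_solvent": None,
                    "premixed": {"volumetric_flow": 1e-6, "C": 0.0,
                                 "w_as": 50.0}},
            network={"total_volume": 1e-6},
            energy={"adiabatic": False})
        res = rx.run_config(cfg)
        assert np.all(res.Y[0, res.network.f_slice] == 0.0)

    def test_steady_state_flow_residuals_small(self):
        res = rx.run_config(make_cfg())
        audit = rx.flow_audit(res)
        for key in ("steady_residual_solute", "steady_residual_solvents",
                    "steady_residual_crystals", "steady_residual_temperature"):
            assert audit[key] < 1e-4, key

    def test_open_species_balance_at_steady_state(self):
        """Inflow - outflow of every species matches the reaction sink."""
        res = rx.run_config(make_cfg())
        net = res.network
        Y = res.Y
        mw = pbe.mass_weights(net.grid, net.constants.rho_crystal,
                              net.constants.k_v)
        out = net.outlet_comp
        q_out = net.Q_outlet[out]
        # solvents are inert: inflow must equal outflow (mean composition)
        for sp, i_sp in ((rx.METHANOL, 5), (rx.WATER, 6)):
            inflow = sum(i.Q * i.conc[sp] for i in net.inlets)
            mean_out = (Y[out, 0] * net.phi1[sp] + Y[out, 1] * net.phi2[sp]
                        + Y[out, i_sp])
            assert q_out * mean_out == pytest.approx(inflow, rel=1e-5)
        # solute inflow = solute outflow + crystal mass outflow
        sol_in = sum(i.Q * i.conc[rx.SOLUTE] for i in net.inlets)
        sol_out = q_out * (Y[out, 0] * net.phi1[rx.SOLUTE] + Y[out, 4])
        cry_out = q_out * float(mw @ np.clip(Y[out, net.f_slice], 0, None))
        assert sol_out + cry_out == pytest.approx(sol_in, rel=1e-5)

    def test_adiabatic_energy_closure(self):
        """Outlet enthalpy rise equals the integrated mixing heat source."""
        res = rx.run_config(make_cfg())
        net = res.network
        rhs = rx.assemble_rhs(net)
        # isolate source terms by evaluating dT/dt minus the flow operator
        T_out = res.Y[net.outlet_comp, net.i_T]
        T_in = (sum(i.Q * i.T for i in net.inlets)
                / sum(i.Q for i in net.inlets))
        # crude closure: temperature rise bounded by -dH_mix / cp and positive
        assert 0.0 < T_out - T_in < -net.dH_mix / net.cp * 1.1


class TestOutletSummary:
    def test_zero_crystals_gives_zero_mass_flow(self):
        cfg = make_cfg(
            template="mixed_cell",
            inlets={"solution": None, "anti_solvent": None,
                    "premixed": {"volumetric_flow": 1e-6, "C": 0.0,
                                 "w_as": 50.0}},
            network={"total_volume": 1e-6},
            energy={"adiabatic": False})
        summary = rx.outlet_summary(rx.run_config(cfg))
        assert summary.outlet_mass_flow_mg_s == 0.0

    def test_imposed_uniform_mass_density_arithmetic(self, default_grid):
        """0.02 kg/m^3 total through 1e-6 m^3/s is 0.02 mg/s."""
        grid = default_grid
        net = ver.msmpr_network(grid, B=1.0, G=1e-9, tau=1.0, Q=1e-6)
        mw = pbe.mass_weights(grid, net.constants.rho_crystal,
                              net.constants.k_v)
        f = np.full(grid.n, 1.0)
        f *= 0.02 / (mw @ f)
        Y = net.initial_state().reshape(net.nc, net.nv).copy()
        Y[0, net.f_slice] = f
        res = rx.ReactorResult(network=net, times=np.array([0.0]),
                               states=Y.reshape(1, -1), converged=True,
                               steady_residual=0.0)
        assert rx.outlet_summary(res).outlet_mass_flow_mg_s == pytest.approx(0.02)


class TestParameterSweep:
    def test_single_value_sweep_equals_direct_run(self):
        cfg = make_cfg()
        table = rx.parameter_sweep(cfg, "inlet_supersaturation", [8.8])
        direct = rx.outlet_summary(rx.run_config(cfg))
        assert len(table) == 1
        assert table.loc[0, "mass_mean_um"] == pytest.approx(
            direct.mass_mean_um, rel=1e-9)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="sweep parameter"):
            rx.parameter_sweep(make_cfg(), "nozzle_count", [1])

    def test_failures_recorded_not_raised(self):
        cfg = make_cfg(solver={"max_residence_times": 1e-6})
        table = rx.parameter_sweep(cfg, "inlet_supersaturation", [8.8])
        assert len(table) == 1
        assert table.loc[0, "error"] != ""
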