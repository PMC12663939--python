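"""Solver oracles and property tests for the two-compartment leaf model."""

import numpy as np
import pytest

from oxzhydro import model as mdl
from oxzhydro import thermo
from oxzhydro.model import (BoundaryConditions, LeafNetwork, MembraneLaw,
                            ScenarioSpec, gs_closure_schedule,
                            membrane_conductance, predict_response_curves,
                            scenario_compare, solve_steady_state,
                            two_node_closed_form)

from conftest import random_law, random_network


def _bc(psi_xyl=-0.85, vpd=3.8, gs=180.0, t=mdl.T_LEAF_DEFAULT,
        gs_ad=None, gs_ab=None):
    air = thermo.air_state_from_vpd(vpd, t)
    if gs_ad is None:
        gs_ad = gs / 2
    if gs_ab is None:
        gs_ab = gs / 2
    return BoundaryConditions(psi_xyl=psi_xyl, air=air, gs_ad=gs_ad, gs_ab=gs_ab)


class TestMembraneLaw:
    def test_limits(self, steep_law):
        assert membrane_conductance(steep_law, 0.0) == pytest.approx(
            steep_law.kappa_max, rel=2e-3)
        assert membrane_conductance(steep_law, -50.0) == pytest.approx(
            steep_law.kappa_min, rel=1e-9)

    def test_midpoint(self, steep_law):
        mid = 0.5 * (steep_law.kappa_max + steep_law.kappa_min)
        assert membrane_conductance(steep_law, steep_law.psi_50) == \
            pytest.approx(mid, rel=1e-12)

    def test_monotone_decreasing_with_stress(self, steep_law):
        psi = np.linspace(-3, 0, 200)
        k = membrane_conductance(steep_law, psi)
        assert np.all(np.diff(k) > 0)  # increasing in psi = decreasing in stress

    def test_extreme_arguments_do_not_overflow(self, steep_law):
        k = membrane_conductance(steep_law, -1e6)
        assert np.isfinite(k) and k == pytest.approx(steep_law.kappa_min)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MembraneLaw(kappa_max=1e-5, kappa_min=1e-3, psi_50=-1, slope=0.1)
        with pytest.raises(ValueError):
            MembraneLaw(kappa_max=1e-3, kappa_min=1e-5, psi_50=-1, slope=-0.1)


class TestValidation:
    def test_negative_gs_rejected(self, default_air):
        with pytest.raises(ValueError):
            BoundaryConditions(psi_xyl=-1.0, air=default_air, gs_ad=-1.0)

    def test_positive_psi_xyl_rejected(self, default_air):
        with pytest.raises(ValueError):
            BoundaryConditions(psi_xyl=0.5, air=default_air)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            ScenarioSpec(kind="osmotic_adjustment")

    def test_network_validation(self):
        with pytest.raises(ValueError):
            LeafNetwork(n_layers=0)
        with pytest.raises(ValueError):
            LeafNetwork(xylem_position=1.5)


class TestSolverOracles:
    def test_taped_leaf_is_in_equilibrium(self, small_network, steep_law):
        """With both surfaces taped (gs = 0) there is no flux and every
        potential equals psi_xyl exactly."""
        bc = _bc(psi_xyl=-1.2, gs_ad=0.0, gs_ab=0.0)
        sol = solve_steady_state(small_network, steep_law, None, bc)
        assert sol.E_total == 0.0
        assert np.allclose(sol.psi_cc, -1.2, atol=1e-9)
        assert np.allclose(sol.psi_apo, -1.2, atol=1e-9)
        assert sol.h_ssc_ad == pytest.approx(
            thermo.psi_to_h(-1.2, bc.air.temperature), abs=1e-12)

    def test_single_layer_matches_closed_form(self):
        """n_layers = 1 must reproduce the independent series-network
        closed form in the solver's linearized mole-fraction space."""
        rng = np.random.default_rng(11)
        t = mdl.T_LEAF_DEFAULT
        for _ in range(100):
            kappa = 10 ** rng.uniform(-5, -3)
            a_int = 10 ** rng.uniform(4, 6)
            gs = rng.uniform(20, 400)
            psi_xyl = rng.uniform(-2, -0.05)
            vpd = rng.uniform(1.0, 4.5)
            net = LeafNetwork(n_layers=1, thickness=2.5e-4, a_int=a_int)
            law = MembraneLaw(kappa_max=kappa, kappa_min=kappa * 0.999,
                              psi_50=-1.0, slope=0.2)
            air = thermo.air_state_from_vpd(vpd, t)
            bc = BoundaryConditions(psi_xyl=psi_xyl, air=air,
                                    gs_ad=gs / 2, gs_ab=gs / 2)
            sol = solve_steady_state(net, law, None, bc)
            # oracle on linearized mole fractions
            beta = thermo.mole_fraction_per_mpa(t)
            kap = membrane_conductance(law, psi_xyl)
            g_oxz_lin = kap * a_int * net.thickness / beta * 1e3  # mmol
            w_sat = air.w_sat
            w_xyl_lin = w_sat + beta * psi_xyl
            w_ssc, e, _ = two_node_closed_form(g_oxz_lin, gs, w_xyl_lin, air.w_a)
            assert sol.E_total == pytest.approx(e, rel=1e-10)
            psi_ssc_lin = (w_ssc - w_sat) / beta
            assert sol.psi_ssc_ad == pytest.approx(psi_ssc_lin, rel=1e-10)

    def test_mass_conservation_on_random_networks(self):
        """Total membrane exchange equals total transpiration for 100
        random networks, laws and boundary conditions."""
        rng = np.random.default_rng(42)
        t = mdl.T_LEAF_DEFAULT
        for _ in range(100):
            net = random_network(rng)
            law = random_law(rng)
            air = thermo.air_state_from_vpd(float(rng.uniform(1, 4.5)), t)
            bc = BoundaryConditions(psi_xyl=float(rng.uniform(-2, -0.05)),
                                    air=air,
                                    gs_ad=float(rng.uniform(0, 200)),
                                    gs_ab=float(rng.uniform(0, 200)))
            sol = solve_steady_state(net, law, None, bc)
            # membrane_exchange is mol m^-3 s^-1 per layer; x dz -> mol m^-2 s^-1
            total_exchange = float(np.sum(sol.membrane_exchange) * net.dz) * 1e3
            assert total_exchange == pytest.approx(sol.E_total, abs=1e-9 +
                                                   1e-9 * abs(sol.E_total))

    def test_infinite_kappa_collapses_disequilibrium(self, small_network):
        """As kappa -> infinity the apoplasm tracks the symplasm and g_oxz
        approaches a kappa-independent series limit."""
        bc = _bc(psi_xyl=-0.85)
        laws = [MembraneLaw(kappa_max=s, kappa_min=s * 0.999, psi_50=-1.0,
                            slope=0.2) for s in (1e1, 1e2)]
        sols = [solve_steady_state(small_network, law, None, bc) for law in laws]
        assert sols[0].max_disequilibrium < 1e-3
        assert sols[1].g_oxz == pytest.approx(sols[0].g_oxz, rel=0.01)

    def test_adaxial_abaxial_symmetry(self, steep_law):
        """Centered xylem, odd layer count, equal surface conductances:
        the solution must be mirror-symmetric."""
        net = LeafNetwork(n_layers=21, xylem_position=0.5)
        sol = solve_steady_state(net, steep_law, None, _bc(psi_xyl=-1.0))
        assert sol.E_ad == pytest.approx(sol.E_ab, rel=1e-12)
        assert np.allclose(sol.psi_apo, sol.psi_apo[::-1], atol=1e-10)
        assert np.allclose(sol.psi_cc, sol.psi_cc[::-1], atol=1e-10)

    def test_one_taped_surface_monotone_vapor_profile(self, steep_law):
        """Taped abaxial surface: all vapor exits adaxially, so the apoplasmic
        potential falls monotonically from the abaxial to the adaxial side."""
        net = LeafNetwork(n_layers=31, xylem_position=0.5)
        bc = _bc(psi_xyl=-0.85, gs_ad=180.0, gs_ab=0.0)
        sol = solve_steady_state(net, steep_law, None, bc)
        assert sol.E_ab == 0.0
        assert sol.E_ad > 0
        assert np.all(np.diff(sol.psi_apo) <= 1e-12)
        assert sol.psi_ssc_ad < sol.psi_ssc_ab

    def test_grid_refinement_converges(self, steep_law):
        """The reported g_oxz converges under grid refinement."""
        bc = _bc(psi_xyl=-0.85)
        g = []
        for n in (25, 50, 100, 200):
            net = LeafNetwork(n_layers=n)
            g.append(solve_steady_state(net, steep_law, None, bc).g_oxz)
        err = [abs(x - g[-1]) for x in g[:-1]]
        assert err[1] < err[0]
        assert abs(g[-2] - g[-1]) / g[-1] < 0.02


class TestSolverMonotonicity:
    def test_goxz_increases_with_membrane_conductance(self, small_network):
        bc = _bc(psi_xyl=-0.85)
        g = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            law = MembraneLaw(kappa_max=1e-3 * scale, kappa_min=1e-5 * scale,
                              psi_50=-1.0, slope=0.15)
            g.append(solve_steady_state(small_network, law, None, bc).g_oxz)
        assert np.all(np.diff(g) > 0)

    def test_transpiration_increases_with_vpd(self, small_network, steep_law):
        e = [solve_steady_state(small_network, steep_law, None,
                                _bc(vpd=v)).E_total
             for v in (1.0, 2.0, 3.0, 4.0)]
        assert np.all(np.diff(e) > 0)

    def test_undersaturation_deepens_with_stress(self, small_network):
        h = [solve_steady_state(small_network, mdl.DEFAULT_LAW, None,
                                _bc(psi_xyl=p)).h_ssc_ad
             for p in (-1.6, -1.2, -0.8, -0.4)]
        assert np.all(np.diff(h) > 0)


class TestTwoNodeClosedForm:
    def test_limits(self):
        w_xyl, w_a = 0.05, 0.02
        # gs -> 0: interior saturates to the xylem state, E -> 0
        w, e, d = two_node_closed_form(1000.0, 0.0, w_xyl, w_a)
        assert (w, e, d) == (w_xyl, 0.0, 0.0)
        # g_oxz >> gs: interior pinned near the xylem state
        w, e, _ = two_node_closed_form(1e9, 100.0, w_xyl, w_a)
        assert w == pytest.approx(w_xyl, rel=1e-6)
        assert e == pytest.approx(100.0 * (w_xyl - w_a), rel=1e-6)

    def test_invalid_conductances(self):
        with pytest.raises(ValueError):
            two_node_closed_form(0.0, 10.0, 0.05, 0.02)
        with pytest.raises(ValueError):
            two_node_closed_form(100.0, -1.0, 0.05, 0.02)


class TestResponseCurves:
    def test_constant_kappa_gives_flat_goxz(self, small_network):
        law = MembraneLaw(kappa_max=1e-4, kappa_min=1e-4 * 0.9999,
                          psi_50=-1.0, slope=0.2)
        df = predict_response_curves(small_network, law, None,
                                     psi_grid=np.linspace(-2, -0.1, 8))
        # a slight psi dependence remains from the exact-Kelvin reporting
        assert np.ptp(df["g_oxz"]) / df["g_oxz"].mean() < 0.02

    def test_closure_schedule_shape(self):
        assert gs_closure_schedule(-1.0) == pytest.approx(180.0)
        assert gs_closure_schedule(-1.8) == pytest.approx(60.0)
        assert gs_closure_schedule(-2.5) == pytest.approx(60.0)
        mid = gs_closure_schedule(-1.65)
        assert 60.0 < mid < 180.0

    def test_closure_produces_humidity_recovery(self):
        """With stomatal closure near the turgor loss point, the deepest
        undersaturation occurs at intermediate stress and h_ssc recovers
        at the most negative psi_xyl (the non-monotone signature)."""
        grid = np.round(np.arange(-2.0, 0.0, 0.1), 10)
        df = predict_response_curves(mdl.DEFAULT_NETWORK, mdl.DEFAULT_LAW,
                                     None, psi_grid=grid,
                                     gs=gs_closure_schedule)
        h = df.set_index("psi_xyl")["h_ssc"]
        assert h.loc[-2.0] > h.loc[-1.5]          # recovery under closure
        assert h.idxmin() not in (grid.min(), grid.max())

    def test_without_closure_no_recovery(self):
        grid = np.round(np.arange(-2.0, 0.0, 0.1), 10)
        df = predict_response_curves(mdl.DEFAULT_NETWORK, mdl.DEFAULT_LAW,
                                     None, psi_grid=grid, gs=180.0)
        assert np.all(np.diff(df["h_ssc"]) > 0)   # monotone in psi_xyl
        assert df.attrs["g_oxz_monotone_in_psi"]

    def test_grid_domain_enforced(self, small_network, steep_law):
        with pytest.raises(ValueError):
            predict_response_curves(small_network, steep_law,
                                    psi_grid=[-3.0, -1.0])


class TestScenarios:
    GRID = (-1.6, -1.2, -0.85, -0.4)

    def _compare(self):
        scens = [ScenarioSpec(k) for k in
                 ("uniform_membrane", "symplasm_conductance",
                  "wall_air_layer", "bundle_sheath_only")]
        return scenario_compare(scens, mdl.DEFAULT_NETWORK, mdl.DEFAULT_LAW,
                                psi_grid=self.GRID)

    def test_wall_air_layer_indistinguishable_from_uniform(self):
        df = self._compare().set_index(["scenario", "psi_xyl"])
        for p in self.GRID:
            a = df.loc[("uniform_membrane", p), "g_oxz"]
            b = df.loc[("wall_air_layer", p), "g_oxz"]
            assert b == pytest.approx(a, rel=1e-3)

    def test_symplasm_scenario_keeps_near_equilibrium(self):
        """If only the cell-to-cell path declined, membranes would keep the
        apoplasm near the symplasm potential -- no large disequilibrium."""
        df = self._compare().set_index(["scenario", "psi_xyl"])
        for p in (-0.85, -1.2, -1.6):
            assert df.loc[("symplasm_conductance", p), "max_diseq"] < 1.0
            assert df.loc[("uniform_membrane", p), "max_diseq"] > 5.0

    def test_bundle_sheath_scenario_violates_mesophyll_turgor(self):
        """Confining the loss to the bundle sheath drags the mesophyll
        symplasm far below the turgor loss point; the distributed-membrane
        scenario keeps the symplasm near the xylem potential."""
        df = self._compare().set_index(["scenario", "psi_xyl"])
        for p in (-0.85, -1.2, -1.6):
            assert not df.loc[("bundle_sheath_only", p), "turgor_ok"]
            assert df.loc[("uniform_membrane", p), "turgor_ok"]
            assert df.loc[("uniform_membrane", p), "min_psi_cc"] > p - 0.2

    def test_needs_at_least_two_scenarios(self):
        with pytest.raises(ValueError):
            scenario_compare([ScenarioSpec()], mdl.DEFAULT_NETWORK,
                             mdl.DEFAULT_LAW)
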