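"""Steady-state engine: Rubisco kinetics, derived metrics, convergence,
conservation laws and the physiological behavior of full runs."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from c4sim import (Drivers, Variant, assimilation, build_model, load_params,
                   photorespiration_rate, rubisco_rates, run_to_steady_state)
from c4sim.steady_state import _apply_drivers


@pytest.fixture(scope="module")
def params():
    return load_params()


class TestRubiscoRates:
    def test_saturating_co2_reaches_vcmax(self, params):
        vc, vo = rubisco_rates(1e9, 0.0, 1e9, params)
        assert vc == pytest.approx(65.0, rel=1e-6)   # table capacity
        assert vo == 0.0

    def test_no_oxygen_no_oxygenation(self, params):
        _, vo = rubisco_rates(40.0, 0.0, 1000.0, params)
        assert vo == 0.0

    def test_half_saturation_point(self, params):
        rub = params["enzymes"]["RUBISCO"]
        gas = params["gas"]
        kc = rub["kc_ubar"] * gas["henry_co2_uM_per_ubar"]
        ko = rub["ko_mbar"] * 1000.0 * gas["henry_o2_uM_per_ubar"]
        o = 264.0
        c_half = kc * (1.0 + o / ko)
        vc, _ = rubisco_rates(c_half, o, 1e12, params)
        assert vc == pytest.approx(32.5, rel=1e-6)

    def test_kinetic_ratio_identity(self, params):
        c, o = 40.0, 300.0
        vc, vo = rubisco_rates(c, o, 900.0, params)
        rub = params["enzymes"]["RUBISCO"]
        gas = params["gas"]
        kc = rub["kc_ubar"] * gas["henry_co2_uM_per_ubar"]
        ko = rub["ko_mbar"] * 1000.0 * gas["henry_o2_uM_per_ubar"]
        vomax = 65.0 * ko / (kc * rub["sco_solution"])
        assert vo / vc == pytest.approx(vomax * kc * o / (65.0 * ko * c),
                                        rel=1e-9)


class TestScalarMetrics:
    @pytest.mark.parametrize("vc,vo,rd,expected",
                             [(40.0, 4.0, 1.0, 37.0),
                              (0.0, 0.0, 1.0, -1.0),
                              (3.0, 4.0, 1.0, 0.0)])
    def test_assimilation_arithmetic(self, vc, vo, rd, expected):
        assert assimilation(vc, vo, rd) == pytest.approx(expected)

    def test_photorespiration_is_half_vo(self):
        assert photorespiration_rate(4.0) == 2.0
        assert photorespiration_rate(0.0) == 0.0


class TestDarkLimit:
    def test_dark_assimilation_equals_minus_respiration(self, std_model):
        """With no light there is no carboxylation: A = -Rd exactly."""
        r = run_to_steady_state(std_model, Drivers(ppfd=0.0))
        assert r.vc == pytest.approx(0.0, abs=1e-9)
        assert r.vo == pytest.approx(0.0, abs=1e-9)
        assert r.A == pytest.approx(-1.0, abs=1e-6)

    def test_dark_respects_custom_rd(self, std_model):
        r = run_to_steady_state(std_model, Drivers(ppfd=0.0, rd=2.0))
        assert r.A == pytest.approx(-2.0, abs=1e-6)


class TestConvergence:
    def test_flux_balance_residual_small_at_convergence(self, std_2000):
        assert std_2000.converged
        assert std_2000.flux_balance_max < 1e-3

    def test_flux_balance_oracle_recomputation(self, std_model, std_2000):
        """Independent stoichiometry x flux loop over the converged state."""
        cn = std_model.compiled
        # restore the drivers of the stored run (the shared compiled model
        # carries per-run light caps)
        _apply_drivers(std_model, std_2000.drivers, std_2000.f_mc,
                       std_2000.let_bsc)
        y = std_2000.state.values
        v = cn.fluxes(y)
        for key, i in cn.pool_index.items():
            net = sum(r.stoichiometry.get(key, 0.0) * v[j]
                      for j, r in enumerate(cn.reactions))
            assert abs(net) < 1e-3, key

    def test_steady_state_is_initial_condition_independent(self, std_model,
                                                           std_2000):
        """Scaling the free metabolite pools does not move the attractor
        (conserved moiety totals are kept, since they parameterize the
        system rather than relax)."""
        cn = std_model.compiled
        y0 = std_model.network.initial_state().values.copy()
        moiety = ("ATP", "ADP", "NADPH", "NADP", "GLU", "OG2")
        for key, i in cn.pool_index.items():
            if key.split("@")[0] not in moiety:
                y0[i] *= 2.0
        r2 = run_to_steady_state(std_model, Drivers(ppfd=2000.0), y0=y0)
        assert r2.A == pytest.approx(std_2000.A, abs=1e-4)

    def test_unconverged_runs_are_reported_not_hidden(self, std_model):
        r = run_to_steady_state(std_model, Drivers(ppfd=2000.0), t_max=1.0)
        assert not r.converged
        assert r.residual > 1e-8


@pytest.fixture(scope="module")
def trajectory(std_model):
    _apply_drivers(std_model, Drivers(ppfd=1500.0), None, None)
    cn = std_model.compiled
    y0 = std_model.network.initial_state().values
    sol = solve_ivp(cn.rhs, (0.0, 500.0), y0, method="LSODA",
                    rtol=1e-8, atol=1e-10,
                    t_eval=np.linspace(0.0, 500.0, 26))
    assert sol.success
    return cn, sol


class TestTrajectoryInvariants:

    @pytest.mark.parametrize("pair,comp", [
        (("NADPH", "NADP"), "MC_CHL"), (("NADPH", "NADP"), "BSC_CHL"),
        (("ATP", "ADP"), "MC_CHL"), (("ATP", "ADP"), "BSC_CHL"),
    ])
    def test_moiety_conservation_along_trajectory(self, trajectory, pair, comp):
        cn, sol = trajectory
        idx = [cn.pool_index[f"{n}@{comp}"] for n in pair]
        total = sol.y[idx].sum(axis=0)
        assert np.max(np.abs(total - total[0])) < 1e-6 * total[0]

    def test_non_negativity_along_trajectory(self, trajectory):
        _, sol = trajectory
        assert sol.y.min() > -1e-9

    def test_michaelis_menten_fluxes_bounded_by_vmax(self, trajectory):
        cn, sol = trajectory
        from c4sim.kinetic_core import RateLaw, _IRREV_LAWS
        for k in range(sol.y.shape[1]):
            v = cn.fluxes(sol.y[:, k])
            for j, r in enumerate(cn.reactions):
                if r.rate_law in _IRREV_LAWS:
                    assert v[j] <= r.params["vmax"] + 1e-9, r.name


class TestPhysiology:
    def test_bundle_sheath_co2_is_concentrated(self, std_2000):
        """The CO2-concentrating mechanism: BSC chloroplast CO2 well above
        the intercellular level at a productive steady state."""
        assert std_2000.A > 20.0
        assert std_2000.C_bsc_chl_CO2_ubar > std_2000.drivers.ci_ubar

    def test_leakiness_in_physiological_range(self, std_1500):
        phi = std_1500.phi
        assert phi is not None and 0.0 < phi < 0.5

    def test_leakiness_declines_with_light(self, std_model, std_2000):
        r500 = run_to_steady_state(std_model, Drivers(ppfd=500.0))
        assert r500.phi > std_2000.phi

    def test_mixed_pathway_raises_leakiness(self, std_2000, mixed_2000):
        """Extra decarboxylation routes speed the C4 cycle and enhance
        overcycling, so the mixed model leaks more."""
        assert mixed_2000.phi > std_2000.phi

    def test_mixed_pathway_suppresses_photorespiration(self, std_2000,
                                                       mixed_2000):
        assert mixed_2000.v_pr < std_2000.v_pr

    def test_mixed_pathway_concentrates_more_co2(self, std_2000, mixed_2000):
        assert mixed_2000.C_bsc_chl_CO2_ubar > std_2000.C_bsc_chl_CO2_ubar

    def test_carbon_closure_overcycling_equals_leak(self, std_2000):
        """Bundle-sheath CO2 balance: decarboxylation + photorespiratory
        release + respiration = carboxylation + leak."""
        f = std_2000.fluxes
        into = (f.get("NADP_ME", 0.0) + f.get("PEPCK", 0.0)
                + f.get("PR_PATH", 0.0) + f.get("RESP_B", 0.0))
        out = std_2000.vc + std_2000.v_leak
        assert into == pytest.approx(out, abs=1e-3)

    def test_amino_group_closure(self, mixed_2000):
        """Net aspartate flux into the bundle sheath returns as alanine."""
        f = mixed_2000.fluxes
        asp_in = f["T_ASP_MC_CYT_BSC_CYT"]
        ala_back = -f["T_ALA_MC_CYT_BSC_CYT"]
        assert asp_in == pytest.approx(ala_back, abs=1e-3)

    def test_malate_is_dominant_transfer_acid_pool(self, std_2000):
        pools = std_2000.pools
        others = [pools.get(m, 0.0) for m in ("PYR", "PEP", "ASP", "ALA")]
        assert pools["MAL"] > max(others)
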