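"""Rate-law library, RHS assembly and stoichiometric bookkeeping."""

import numpy as np
import pytest

from c4sim.kinetic_core import (AMINO_COUNT, CARBON_COUNT, Compartment,
                                CompiledNetwork, ConfigurationError,
                                MetabolitePool, ModelState, Network, RateLaw,
                                ReactionSpec, StateError, build_rhs, pool_key,
                                rate, stoichiometric_audit)

C = Compartment.MC_CYT


def _state(**conc):
    keys = list(conc)
    return ModelState(values=np.array([conc[k] for k in keys], dtype=float),
                      index={k: i for i, k in enumerate(keys)})


class TestIrreversibleMM:
    def test_zero_substrate_gives_zero_flux(self):
        r = ReactionSpec("ME", {"S@MC_CYT": -1.0}, RateLaw.IRREV_MM_1S,
                         {"vmax": 90.0, "substrates": [("S@MC_CYT", 200.0)]})
        assert rate(r, _state(**{"S@MC_CYT": 0.0})) == 0.0

    def test_saturation_limit_is_vmax(self):
        # Vmax 90 is the malic-enzyme capacity of the parameter table
        r = ReactionSpec("ME", {"S@MC_CYT": -1.0}, RateLaw.IRREV_MM_1S,
                         {"vmax": 90.0, "substrates": [("S@MC_CYT", 200.0)]})
        assert rate(r, _state(**{"S@MC_CYT": 1e12})) == pytest.approx(90.0, rel=1e-9)

    def test_bisubstrate_half_saturation(self):
        # both substrates at their Km: v = Vmax * 0.5 * 0.5
        r = ReactionSpec("PEPC", {"A@MC_CYT": -1.0, "B@MC_CYT": -1.0},
                         RateLaw.IRREV_MM_2S,
                         {"vmax": 170.0, "substrates": [("A@MC_CYT", 80.0),
                                                        ("B@MC_CYT", 15.0)]})
        v = rate(r, _state(**{"A@MC_CYT": 80.0, "B@MC_CYT": 15.0}))
        assert v == pytest.approx(170.0 * 0.25, rel=1e-12)

    def test_inhibitor_halves_flux_at_ki(self):
        r = ReactionSpec("E", {"S@MC_CYT": -1.0}, RateLaw.IRREV_MM_1S,
                         {"vmax": 10.0, "substrates": [("S@MC_CYT", 1e-6)],
                          "inhibitors": [("I@MC_CYT", 100.0)]})
        v = rate(r, _state(**{"S@MC_CYT": 1.0, "I@MC_CYT": 100.0}))
        assert v == pytest.approx(5.0, rel=1e-5)

    def test_negative_state_rejected(self):
        r = ReactionSpec("E", {"S@MC_CYT": -1.0}, RateLaw.IRREV_MM_1S,
                         {"vmax": 1.0, "substrates": [("S@MC_CYT", 1.0)]})
        with pytest.raises(StateError):
            rate(r, _state(**{"S@MC_CYT": -1.0}))

    def test_unknown_rate_law_rejected(self):
        r = ReactionSpec("E", {"S@MC_CYT": -1.0}, RateLaw.IRREV_MM_1S,
                         {"vmax": 1.0, "substrates": [("S@MC_CYT", 1.0)]})
        r.rate_law = "nonsense"
        with pytest.raises((ConfigurationError, AttributeError)):
            rate(r, _state(**{"S@MC_CYT": 1.0}))


class TestReversibleMM:
    def _rxn(self, keq=2.0):
        return ReactionSpec(
            "R", {"S@MC_CYT": -1.0, "P@MC_CYT": +1.0}, RateLaw.REV_MM,
            {"vmax": 10.0, "keq": keq,
             "substrates": [("S@MC_CYT", 100.0)],
             "products": [("P@MC_CYT", 200.0)]})

    def test_flux_vanishes_at_equilibrium(self):
        v = rate(self._rxn(), _state(**{"S@MC_CYT": 50.0, "P@MC_CYT": 100.0}))
        assert v == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("s,p,sign", [(100.0, 50.0, 1), (10.0, 150.0, -1)])
    def test_sign_follows_displacement(self, s, p, sign):
        v = rate(self._rxn(), _state(**{"S@MC_CYT": s, "P@MC_CYT": p}))
        assert np.sign(v) == sign


class TestSpecialLaws:
    def test_diffusion_is_linear_in_gradient(self):
        r = ReactionSpec("T", {"A@MC_CYT": -1.0, "A@BSC_CYT": +1.0},
                         RateLaw.DIFFUSION,
                         {"g": 0.1, "source": "A@MC_CYT", "target": "A@BSC_CYT"})
        st = _state(**{"A@MC_CYT": 300.0, "A@BSC_CYT": 100.0})
        assert rate(r, st) == pytest.approx(20.0)
        st2 = _state(**{"A@MC_CYT": 100.0, "A@BSC_CYT": 300.0})
        assert rate(r, st2) == pytest.approx(-20.0)

    def test_rubisco_pair_respects_kinetic_ratio(self):
        # vo/vc = (Vomax*Kc*O)/(Vcmax*Ko*C) must hold exactly
        pools = {"co2": "CO2@BSC_CHL", "o2": "O2@BSC_CHL", "rubp": "RUBP@BSC_CHL"}
        pc = {"vcmax": 65.0, "kc": 21.7, "ko": 567.0, "km_rubp": 200.0, **pools}
        po = {"vomax": 20.0, "kc": 21.7, "ko": 567.0, "km_rubp": 200.0, **pools}
        rc = ReactionSpec("vc", {"CO2@BSC_CHL": -1.0}, RateLaw.RUBISCO_C, pc)
        ro = ReactionSpec("vo", {"O2@BSC_CHL": -1.0}, RateLaw.RUBISCO_O, po)
        st = _state(**{"CO2@BSC_CHL": 40.0, "O2@BSC_CHL": 300.0,
                       "RUBP@BSC_CHL": 800.0})
        vc, vo = rate(rc, st), rate(ro, st)
        expected = (20.0 * 21.7 * 300.0) / (65.0 * 567.0 * 40.0)
        assert vo / vc == pytest.approx(expected, rel=1e-9)


class TestBuildRhs:
    def test_single_reaction_signed_derivatives(self):
        pools = [MetabolitePool("A", C, 100.0), MetabolitePool("B", C, 0.0)]
        rxn = ReactionSpec("step", {"A@MC_CYT": -1.0, "B@MC_CYT": +1.0},
                           RateLaw.MASS_ACTION,
                           {"k": 0.5, "keq": float("inf"),
                            "substrate": "A@MC_CYT", "product": "B@MC_CYT"})
        rhs, cn = build_rhs([rxn], pools, {C: 1.0})
        dy = rhs(0.0, np.array([100.0, 0.0]))
        assert dy[cn.pool_index["A@MC_CYT"]] == pytest.approx(-50.0)
        assert dy[cn.pool_index["B@MC_CYT"]] == pytest.approx(+50.0)

    def test_volume_scaling(self):
        pools = [MetabolitePool("A", C, 100.0), MetabolitePool("B", C, 0.0)]
        rxn = ReactionSpec("step", {"A@MC_CYT": -1.0, "B@MC_CYT": +1.0},
                           RateLaw.MASS_ACTION,
                           {"k": 0.5, "keq": float("inf"),
                            "substrate": "A@MC_CYT", "product": "B@MC_CYT"})
        rhs, cn = build_rhs([rxn], pools, {C: 0.02})
        dy = rhs(0.0, np.array([100.0, 0.0]))
        assert dy[cn.pool_index["A@MC_CYT"]] == pytest.approx(-50.0 / 0.02)

    def test_orphan_pool_rejected(self):
        pools = [MetabolitePool("A", C, 1.0), MetabolitePool("Z", C, 1.0)]
        rxn = ReactionSpec("decay", {"A@MC_CYT": -1.0}, RateLaw.IRREV_MM_1S,
                           {"vmax": 1.0, "substrates": [("A@MC_CYT", 1.0)]},
                           boundary=True)
        with pytest.raises(ConfigurationError, match="orphan"):
            build_rhs([rxn], pools, {C: 1.0})

    def test_undeclared_pool_rejected(self):
        pools = [MetabolitePool("A", C, 1.0)]
        rxn = ReactionSpec("step", {"A@MC_CYT": -1.0, "GHOST@MC_CYT": 1.0},
                           RateLaw.IRREV_MM_1S,
                           {"vmax": 1.0, "substrates": [("A@MC_CYT", 1.0)]})
        with pytest.raises(ConfigurationError, match="undeclared"):
            build_rhs([rxn], pools, {C: 1.0})

    def test_clamped_pool_held_constant(self):
        pools = [MetabolitePool("A", C, 100.0, clamped=True),
                 MetabolitePool("B", C, 0.0)]
        rxn = ReactionSpec("step", {"A@MC_CYT": -1.0, "B@MC_CYT": +1.0},
                           RateLaw.MASS_ACTION,
                           {"k": 0.5, "keq": float("inf"),
                            "substrate": "A@MC_CYT", "product": "B@MC_CYT"})
        rhs, cn = build_rhs([rxn], pools, {C: 1.0})
        assert "A@MC_CYT" not in cn.pool_index   # not part of the state
        dy = rhs(0.0, np.array([0.0]))
        assert dy[cn.pool_index["B@MC_CYT"]] == pytest.approx(50.0)

    def test_scalar_and_vectorized_rates_agree(self):
        """The compiled network must reproduce the reference scalar laws."""
        from c4sim.pathway_variants import Variant, build_model
        model = build_model(Variant.ASP_MAL_PEPCK_ME)
        cn = model.compiled
        rng = np.random.default_rng(7)
        y = rng.uniform(1.0, 2000.0, size=len(cn.pool_index))
        v_vec = cn.fluxes(y)
        st = cn.state(y)
        for j, rxn in enumerate(cn.reactions):
            assert rate(rxn, st) == pytest.approx(v_vec[j], rel=1e-9, abs=1e-12), rxn.name

    def test_rhs_matches_brute_force_stoichiometry_product(self):
        """Flux balance: RHS equals the signed stoichiometry x flux sum."""
        from c4sim.pathway_variants import Variant, build_model
        model = build_model(Variant.NADP_ME_STANDARD)
        cn = model.compiled
        rng = np.random.default_rng(11)
        y = rng.uniform(1.0, 500.0, size=len(cn.pool_index))
        v = cn.fluxes(y)
        dy = cn.rhs(0.0, y)
        vols = model.params["compartments"]
        for key, i in cn.pool_index.items():
            acc = 0.0
            for j, rxn in enumerate(cn.reactions):
                acc += rxn.stoichiometry.get(key, 0.0) * v[j]
            comp = key.split("@")[1]
            assert dy[i] == pytest.approx(acc / vols[comp], rel=1e-9, abs=1e-9)


class TestAudit:
    def test_pepc_carbon_balanced(self):
        r = ReactionSpec("PEPC", {pool_key("PEP", C): -1.0,
                                  pool_key("HCO3", C): -1.0,
                                  pool_key("OAA", C): +1.0},
                         RateLaw.IRREV_MM_2S,
                         {"vmax": 1.0, "substrates": [(pool_key("PEP", C), 1.0),
                                                      (pool_key("HCO3", C), 1.0)]})
        report = stoichiometric_audit([r])
        assert report.carbon_balance["PEPC"] == 0
        assert report.ok

    def test_transaminase_amino_group_balanced(self):
        r = ReactionSpec("AspAT", {pool_key("OAA", C): -1.0,
                                   pool_key("GLU", C): -1.0,
                                   pool_key("ASP", C): +1.0,
                                   pool_key("OG2", C): +1.0},
                         RateLaw.REV_MM,
                         {"vmax": 1.0, "keq": 6.6,
                          "substrates": [(pool_key("OAA", C), 1.0),
                                         (pool_key("GLU", C), 1.0)],
                          "products": [(pool_key("ASP", C), 1.0),
                                       (pool_key("OG2", C), 1.0)]})
        report = stoichiometric_audit([r])
        assert report.amino_balance["AspAT"] == 0
        assert report.ok

    def test_corrupted_stoichiometry_flagged(self):
        # OAA -> PEP without releasing CO2 destroys a carbon
        r = ReactionSpec("broken", {pool_key("OAA", C): -1.0,
                                    pool_key("PEP", C): +1.0},
                         RateLaw.IRREV_MM_1S,
                         {"vmax": 1.0, "substrates": [(pool_key("OAA", C), 1.0)]})
        report = stoichiometric_audit([r])
        assert "broken" in report.flagged
        assert not report.ok

    def test_full_network_is_balanced(self):
        from c4sim.pathway_variants import Variant, build_variant
        for variant in Variant:
            _, net = build_variant(variant)
            report = stoichiometric_audit(net.reactions)
            assert report.ok, (variant, report.flagged)
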