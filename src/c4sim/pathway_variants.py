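"""Construction of the five C4 pathway-variant models.

All variants share one reaction catalog — the classical NADP-ME malate
shuttle plus aspartate/alanine aminotransfer, PEP carboxykinase, the
bundle-sheath Calvin cycle and the intercellular diffusion links — and
differ only in which enzyme capacities are switched on:

========================  =====  =====  =====  =====  =====  ======
variant                   MDH_M  MDH_B  NADPME PEPCK  AspAT  AlaAT
NADP_ME_STANDARD            x      -      x      -      -      -
ASP_MAL_ME                  x      x      x      -      x      x
ASP_MAL_PEPCK               x      -      x      x      x      x
ASP_MAL_PEPCK_ME            x      x      x      x      x      x
ASP_PEPCK_ONLY              -      -      -      x      x      x
========================  =====  =====  =====  =====  =====  ======

Mesophyll (MC) and bundle-sheath (BSC) metabolites live in the respective
cytosol pools; each cell's chloroplast carries the ATP/ADP and NADPH/NADP
pools (envelope transport of small metabolites is lumped into the enzyme
steps, except for the bundle-sheath chloroplast's PGA/TP export carriers
and CO2 diffusion, which are explicit because the site of CO2 release —
stroma for NADP-ME, cytosol for PEPCK — is central to the physiology).
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field

from .kinetic_core import (CARBON_COUNT, Compartment, ConfigurationError,
                           CompiledNetwork, MetabolitePool, Network, RateLaw,
                           ReactionSpec, pool_key)
from .params import load_params
from .transport import TransportSpec, make_diffusion_reaction

__all__ = ["Variant", "PathwayConfig", "build_variant", "build_model",
           "C4Model", "calibrate_asp_share", "TRANSFER_ACIDS"]

MC, MCH, BC, BCH = (Compartment.MC_CYT, Compartment.MC_CHL,
                    Compartment.BSC_CYT, Compartment.BSC_CHL)

#: metabolites whose MC/BSC gradients are reported
TRANSFER_ACIDS = ("MAL", "ASP", "ALA", "PYR", "PEP", "PGA", "TP")


class Variant(str, enum.Enum):
    NADP_ME_STANDARD = "nadp_me"
    ASP_MAL_ME = "asp_mal_me"
    ASP_MAL_PEPCK = "asp_mal_pepck"
    ASP_MAL_PEPCK_ME = "asp_mal_pepck_me"
    ASP_PEPCK_ONLY = "asp_pepck_only"


_SWITCHABLE = ("MDH_M", "MDH_B", "NADP_ME", "PEPCK",
               "AspAT_M", "AspAT_B", "AlaAT_M", "AlaAT_B")

_FORCED_OFF: dict[Variant, frozenset[str]] = {
    Variant.NADP_ME_STANDARD: frozenset(
        {"MDH_B", "PEPCK", "AspAT_M", "AspAT_B", "AlaAT_M", "AlaAT_B"}),
    Variant.ASP_MAL_ME: frozenset({"PEPCK"}),
    Variant.ASP_MAL_PEPCK: frozenset({"MDH_B"}),
    Variant.ASP_MAL_PEPCK_ME: frozenset(),
    # The PEPCK-only pathway returns carbon as PEP itself, so PPDK is not
    # part of its cycle; the pyruvate pool exists purely as the alanine
    # shuttle's counter-carrier (keeping PPDK active would drain it and
    # starve the amino-group return).
    Variant.ASP_PEPCK_ONLY: frozenset({"MDH_M", "MDH_B", "NADP_ME", "PPDK"}),
}

#: variants that transfer both aspartate and malate (aspartate-share
#: calibration applies to these)
ASP_MAL_VARIANTS = (Variant.ASP_MAL_ME, Variant.ASP_MAL_PEPCK,
                    Variant.ASP_MAL_PEPCK_ME)


@dataclass
class PathwayConfig:
    variant: Variant
    enzyme_caps: dict[str, float]
    asp_flux_target: float = 0.25
    aspat_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.asp_flux_target < 1.0:
            raise ConfigurationError("asp_flux_target must lie in [0, 1)")


def _variant_caps(variant: Variant, params: dict,
                  overrides: dict[str, float] | None) -> tuple[dict, float]:
    enz = params["enzymes"]
    caps = {name: enz[name]["vmax"] for name in _SWITCHABLE}
    caps.update({
        "PEPC": enz["PEPC"]["vmax"],
        "PPDK": enz["PPDK"]["vmax"],
        "RUBISCO": enz["RUBISCO"]["vcmax"],
    })
    for name in _FORCED_OFF[variant]:
        caps[name] = 0.0
    scale = 1.0
    if variant in ASP_MAL_VARIANTS:
        scale = params["pathway"]["aspat_scale"].get(variant.name, 1.0)
    if overrides:
        for name, vmax in overrides.items():
            if name not in caps:
                raise ConfigurationError(f"unknown enzyme override {name!r}")
            if name in _FORCED_OFF[variant] and vmax != 0.0:
                raise ConfigurationError(
                    f"{name} is structurally absent from {variant.name}")
            if vmax < 0:
                raise ConfigurationError("Vmax override must be >= 0")
            caps[name] = float(vmax)
    return caps, scale


def _pool_catalog(params: dict) -> dict[str, MetabolitePool]:
    ini = params["initial"]
    gas = params["gas"]
    default = ini["default_uM"]
    o2_amb = gas["henry_o2_uM_per_ubar"] * gas["o2_ambient_mbar"] * 1000.0
    co2_mc = gas["henry_co2_uM_per_ubar"] * params["drivers"]["ci_ubar"]

    def mk(name, comp, conc=None, clamped=False):
        c = conc if conc is not None else ini.get(name, default)
        return MetabolitePool(name, comp, concentration=c, clamped=clamped)

    pools = [
        mk("CO2", MC, co2_mc, clamped=True),   # Ci boundary condition
        mk("O2", MC, o2_amb, clamped=True),    # ambient O2 reference
        *(mk(n, MC) for n in ("HCO3", "PEP", "OAA", "MAL", "PYR", "ASP",
                              "ALA", "GLU", "OG2", "PGA", "TP")),
        *(mk(n, MCH) for n in ("ATP", "ADP", "NADPH", "NADP")),
        *(mk(n, BC) for n in ("CO2", "PEP", "OAA", "MAL", "PYR", "ASP",
                              "ALA", "GLU", "OG2", "PGA", "TP")),
        *(mk(n, BCH) for n in ("CO2", "RUBP", "PGLY", "PGA", "TP",
                               "ATP", "ADP", "NADPH", "NADP")),
        mk("O2", BCH, o2_amb),
    ]
    return {p.key: p for p in pools}


def _k(name: str, comp: Compartment) -> str:
    return pool_key(name, comp)


def _reaction_catalog(params: dict, caps: dict[str, float],
                      aspat_scale: float) -> list[ReactionSpec]:
    """Every reaction of the shared network, with variant capacities."""
    enz = params["enzymes"]
    tr = params["transport"]
    ca = params["carbonic_anhydrase"]
    rd_half = params["drivers"]["rd"] / 2.0

    def irrev(name, cap, subs, stoich, law=None, boundary=False):
        law = law or {1: RateLaw.IRREV_MM_1S, 2: RateLaw.IRREV_MM_2S,
                      3: RateLaw.IRREV_MM_3S}[len(subs)]
        return ReactionSpec(name, stoich, law,
                            {"vmax": cap, "substrates": subs},
                            boundary=boundary)

    def rev(name, cap, subs, prods, keq, stoich):
        return ReactionSpec(name, stoich, RateLaw.REV_MM,
                            {"vmax": cap, "substrates": subs,
                             "products": prods, "keq": keq})

    km = {n: enz[n]["km"] for n in enz if "km" in enz[n]}
    R: list[ReactionSpec] = []

    # --- mesophyll -------------------------------------------------------
    R.append(ReactionSpec(
        "CA", {_k("CO2", MC): -1.0, _k("HCO3", MC): +1.0},
        RateLaw.MASS_ACTION,
        {"k": ca["k"], "keq": ca["keq"],
         "substrate": _k("CO2", MC), "product": _k("HCO3", MC)}))
    pepc = irrev(
        "PEPC", caps["PEPC"],
        [(_k("PEP", MC), km["PEPC"]["PEP"]), (_k("HCO3", MC), km["PEPC"]["HCO3"])],
        {_k("PEP", MC): -1.0, _k("HCO3", MC): -1.0, _k("OAA", MC): +1.0})
    # C4-acid feedback on PEPC, restricted to pools the variant carries
    ki = enz["PEPC"].get("ki", {})
    inhibitors = []
    if "MAL" in ki and (caps["MDH_M"] > 0 or caps["MDH_B"] > 0):
        inhibitors.append((_k("MAL", MC), ki["MAL"]))
    if "ASP" in ki and caps["AspAT_M"] > 0:
        inhibitors.append((_k("ASP", MC), ki["ASP"]))
    if "OAA" in ki:
        inhibitors.append((_k("OAA", MC), ki["OAA"]))
    pepc.params["inhibitors"] = inhibitors
    R.append(pepc)
    R.append(rev(
        "MDH_M", caps["MDH_M"],
        [(_k("OAA", MC), km["MDH_M"]["OAA"]), (_k("NADPH", MCH), km["MDH_M"]["NADPH"])],
        [(_k("MAL", MC), km["MDH_M"]["MAL"]), (_k("NADP", MCH), km["MDH_M"]["NADP"])],
        enz["MDH_M"]["keq"],
        {_k("OAA", MC): -1.0, _k("NADPH", MCH): -1.0,
         _k("MAL", MC): +1.0, _k("NADP", MCH): +1.0}))
    R.append(rev(
        "AspAT_M", caps["AspAT_M"] * aspat_scale,
        [(_k("OAA", MC), km["AspAT_M"]["OAA"]), (_k("GLU", MC), km["AspAT_M"]["GLU"])],
        [(_k("ASP", MC), km["AspAT_M"]["ASP"]), (_k("OG2", MC), km["AspAT_M"]["OG2"])],
        enz["AspAT_M"]["keq"],
        {_k("OAA", MC): -1.0, _k("GLU", MC): -1.0,
         _k("ASP", MC): +1.0, _k("OG2", MC): +1.0}))
    R.append(rev(
        "AlaAT_M", caps["AlaAT_M"],
        [(_k("ALA", MC), km["AlaAT_M"]["ALA"]), (_k("OG2", MC), km["AlaAT_M"]["OG2"])],
        [(_k("PYR", MC), km["AlaAT_M"]["PYR"]), (_k("GLU", MC), km["AlaAT_M"]["GLU"])],
        enz["AlaAT_M"]["keq"],
        {_k("ALA", MC): -1.0, _k("OG2", MC): -1.0,
         _k("PYR", MC): +1.0, _k("GLU", MC): +1.0}))
    R.append(irrev(
        "PPDK", caps["PPDK"],
        [(_k("PYR", MC), km["PPDK"]["PYR"]), (_k("ATP", MCH), km["PPDK"]["ATP"])],
        {_k("PYR", MC): -1.0, _k("ATP", MCH): -2.0,
         _k("PEP", MC): +1.0, _k("ADP", MCH): +2.0}))
    R.append(rev(
        "PGA_RED_M", enz["PGA_RED_M"]["vmax"],
        [(_k("PGA", MC), km["PGA_RED_M"]["PGA"]),
         (_k("ATP", MCH), km["PGA_RED_M"]["ATP"]),
         (_k("NADPH", MCH), km["PGA_RED_M"]["NADPH"])],
        [(_k("TP", MC), km["PGA_RED_M"]["TP"]),
         (_k("ADP", MCH), km["PGA_RED_M"]["ADP"]),
         (_k("NADP", MCH), km["PGA_RED_M"]["NADP"])],
        enz["PGA_RED_M"]["keq"],
        {_k("PGA", MC): -1.0, _k("ATP", MCH): -1.0, _k("NADPH", MCH): -1.0,
         _k("TP", MC): +1.0, _k("ADP", MCH): +1.0, _k("NADP", MCH): +1.0}))
    R.append(rev(
        "ENOLASE", enz["ENOLASE"]["vmax"],
        [(_k("PGA", MC), km["ENOLASE"]["PGA"])],
        [(_k("PEP", MC), km["ENOLASE"]["PEP"])],
        enz["ENOLASE"]["keq"],
        {_k("PGA", MC): -1.0, _k("PEP", MC): +1.0}))
    # supply-regulated sink: cooperativity 2 keeps it idle at low TP
    # (realized as a squared Michaelis-Menten saturation)
    R.append(irrev(
        "SUCROSE_SINK", enz["SUCROSE_SINK"]["vmax"],
        [(_k("TP", MC), km["SUCROSE_SINK"]["TP"])] * enz["SUCROSE_SINK"]["hill"],
        {_k("TP", MC): -1.0}, boundary=True))
    # mitochondrial respiration: constant-rate boundary CO2 source (the
    # substrate is storage carbohydrate outside the modeled pools); the
    # clamped ambient O2 pool serves as the formal substrate so the rate
    # law saturates at Rm immediately
    R.append(irrev(
        "RESP_M", rd_half,
        [(_k("O2", MC), 1e-9)],
        {_k("CO2", MC): +1.0}, boundary=True))
    R.append(irrev(
        "NADPH_OX_M", enz["NADPH_OXIDASE"]["vmax"],
        [(_k("NADPH", MCH), km["NADPH_OXIDASE"]["NADPH"])],
        {_k("NADPH", MCH): -1.0, _k("NADP", MCH): +1.0}))
    R.append(ReactionSpec(
        "ATP_SYNTH_M", {_k("ADP", MCH): -1.0, _k("ATP", MCH): +1.0},
        RateLaw.LIGHT_SYNTHESIS,
        {"vmax": 0.0, "substrate": _k("ADP", MCH), "km": params["light"]["synth_km_uM"]}))
    R.append(ReactionSpec(
        "NADPH_SYNTH_M", {_k("NADP", MCH): -1.0, _k("NADPH", MCH): +1.0},
        RateLaw.LIGHT_SYNTHESIS,
        {"vmax": 0.0, "substrate": _k("NADP", MCH), "km": params["light"]["synth_km_uM"]}))

    # --- bundle sheath ---------------------------------------------------
    # BSC transaminases are written in their operating direction so the
    # Table-1 capacity applies where the flux actually runs (the compact
    # reversible law has Haldane-implied reverse capacity Vf*KmS/(KmP*Keq)).
    R.append(rev(
        "AspAT_B", caps["AspAT_B"],
        [(_k("ASP", BC), km["AspAT_B"]["ASP"]), (_k("OG2", BC), km["AspAT_B"]["OG2"])],
        [(_k("OAA", BC), km["AspAT_B"]["OAA"]), (_k("GLU", BC), km["AspAT_B"]["GLU"])],
        enz["AspAT_B"]["keq"],
        {_k("ASP", BC): -1.0, _k("OG2", BC): -1.0,
         _k("OAA", BC): +1.0, _k("GLU", BC): +1.0}))
    R.append(rev(
        "AlaAT_B", caps["AlaAT_B"],
        [(_k("PYR", BC), km["AlaAT_B"]["PYR"]), (_k("GLU", BC), km["AlaAT_B"]["GLU"])],
        [(_k("ALA", BC), km["AlaAT_B"]["ALA"]), (_k("OG2", BC), km["AlaAT_B"]["OG2"])],
        enz["AlaAT_B"]["keq"],
        {_k("PYR", BC): -1.0, _k("GLU", BC): -1.0,
         _k("ALA", BC): +1.0, _k("OG2", BC): +1.0}))
    R.append(rev(
        "MDH_B", caps["MDH_B"],
        [(_k("OAA", BC), km["MDH_B"]["OAA"]), (_k("NADPH", BCH), km["MDH_B"]["NADPH"])],
        [(_k("MAL", BC), km["MDH_B"]["MAL"]), (_k("NADP", BCH), km["MDH_B"]["NADP"])],
        enz["MDH_B"]["keq"],
        {_k("OAA", BC): -1.0, _k("NADPH", BCH): -1.0,
         _k("MAL", BC): +1.0, _k("NADP", BCH): +1.0}))
    me = irrev(
        "NADP_ME", caps["NADP_ME"],
        [(_k("MAL", BC), km["NADP_ME"]["MAL"]), (_k("NADP", BCH), km["NADP_ME"]["NADP"])],
        {_k("MAL", BC): -1.0, _k("NADP", BCH): -1.0, _k("PYR", BC): +1.0,
         _k("CO2", BCH): +1.0, _k("NADPH", BCH): +1.0})
    me.params["inhibitors"] = [
        (_k("PYR", BC), enz["NADP_ME"]["ki"]["PYR"])]
    R.append(me)
    R.append(irrev(
        "PEPCK", caps["PEPCK"],
        [(_k("OAA", BC), km["PEPCK"]["OAA"]), (_k("ATP", BCH), km["PEPCK"]["ATP"])],
        {_k("OAA", BC): -1.0, _k("ATP", BCH): -1.0, _k("PEP", BC): +1.0,
         _k("CO2", BC): +1.0, _k("ADP", BCH): +1.0}))

    rub = enz["RUBISCO"]
    gasp = params["gas"]
    kc = rub["kc_ubar"] * gasp["henry_co2_uM_per_ubar"]
    ko = rub["ko_mbar"] * 1000.0 * gasp["henry_o2_uM_per_ubar"]
    vomax = caps["RUBISCO"] * ko / (kc * rub["sco_solution"])
    rub_pools = {"co2": _k("CO2", BCH), "o2": _k("O2", BCH),
                 "rubp": _k("RUBP", BCH)}
    R.append(ReactionSpec(
        "RUBISCO_C",
        {_k("RUBP", BCH): -1.0, _k("CO2", BCH): -1.0, _k("PGA", BCH): +2.0},
        RateLaw.RUBISCO_C,
        {"vcmax": caps["RUBISCO"], "kc": kc, "ko": ko,
         "km_rubp": rub["km_rubp"], **rub_pools}))
    R.append(ReactionSpec(
        "RUBISCO_O",
        {_k("RUBP", BCH): -1.0, _k("O2", BCH): -1.0,
         _k("PGA", BCH): +1.0, _k("PGLY", BCH): +1.0},
        RateLaw.RUBISCO_O,
        {"vomax": vomax, "kc": kc, "ko": ko,
         "km_rubp": rub["km_rubp"], **rub_pools}))
    R.append(rev(
        "PGA_RED_B", enz["PGA_RED_B"]["vmax"],
        [(_k("PGA", BCH), km["PGA_RED_B"]["PGA"]),
         (_k("ATP", BCH), km["PGA_RED_B"]["ATP"]),
         (_k("NADPH", BCH), km["PGA_RED_B"]["NADPH"])],
        [(_k("TP", BCH), km["PGA_RED_B"]["TP"]),
         (_k("ADP", BCH), km["PGA_RED_B"]["ADP"]),
         (_k("NADP", BCH), km["PGA_RED_B"]["NADP"])],
        enz["PGA_RED_B"]["keq"],
        {_k("PGA", BCH): -1.0, _k("ATP", BCH): -1.0, _k("NADPH", BCH): -1.0,
         _k("TP", BCH): +1.0, _k("ADP", BCH): +1.0, _k("NADP", BCH): +1.0}))
    regen = irrev(
        "RUBP_REGEN", enz["RUBP_REGEN"]["vmax"],
        [(_k("TP", BCH), km["RUBP_REGEN"]["TP"]),
         (_k("ATP", BCH), km["RUBP_REGEN"]["ATP"])],
        {_k("TP", BCH): -5.0, _k("ATP", BCH): -3.0,
         _k("RUBP", BCH): +3.0, _k("ADP", BCH): +3.0})
    regen.params["inhibitors"] = [
        (_k("RUBP", BCH), enz["RUBP_REGEN"]["ki"]["RUBP"])]
    R.append(regen)
    R.append(irrev(
        "PR_PATH", enz["PR_PATH"]["vmax"],
        [(_k("PGLY", BCH), km["PR_PATH"]["PGLY"])],
        {_k("PGLY", BCH): -2.0, _k("ATP", BCH): -1.0, _k("NADPH", BCH): -0.5,
         _k("PGA", BCH): +1.0, _k("CO2", BC): +1.0,
         _k("ADP", BCH): +1.0, _k("NADP", BCH): +0.5}))
    # water-water cycle: the overflow electrons reduce O2 back to water,
    # so valve-cycled electrons contribute no net O2 evolution
    R.append(irrev(
        "NADPH_OX_B", enz["NADPH_OXIDASE"]["vmax"],
        [(_k("NADPH", BCH), km["NADPH_OXIDASE"]["NADPH"])],
        {_k("NADPH", BCH): -1.0, _k("NADP", BCH): +1.0,
         _k("O2", BCH): -0.5}))
    R.append(irrev(
        "STARCH_SINK", enz["STARCH_SINK"]["vmax"],
        [(_k("TP", BCH), km["STARCH_SINK"]["TP"])] * enz["STARCH_SINK"]["hill"],
        {_k("TP", BCH): -1.0}, boundary=True))
    R.append(irrev(
        "RESP_B", rd_half,
        [(_k("O2", MC), 1e-9)],
        {_k("CO2", BC): +1.0}, boundary=True))
    R.append(ReactionSpec(
        "ATP_SYNTH_B", {_k("ADP", BCH): -1.0, _k("ATP", BCH): +1.0},
        RateLaw.LIGHT_SYNTHESIS,
        {"vmax": 0.0, "substrate": _k("ADP", BCH), "km": params["light"]["synth_km_uM"]}))
    R.append(ReactionSpec(
        "NADPH_SYNTH_B",
        {_k("NADP", BCH): -1.0, _k("NADPH", BCH): +1.0, _k("O2", BCH): +0.5},
        RateLaw.LIGHT_SYNTHESIS,
        {"vmax": 0.0, "substrate": _k("NADP", BCH), "km": params["light"]["synth_km_uM"]}))

    # --- envelope and intercellular transport ----------------------------
    R.append(make_diffusion_reaction(
        TransportSpec("PGA", BCH, BC, tr["g_chl_pga"])))
    R[-1].name = "PGA_ENV_B"
    R.append(make_diffusion_reaction(
        TransportSpec("TP", BCH, BC, tr["g_chl_tp"])))
    R[-1].name = "TP_ENV_B"
    R.append(make_diffusion_reaction(
        TransportSpec("CO2", BCH, BC, tr["g_chl_co2"])))
    R[-1].name = "CO2_ENV_B"

    for met in TRANSFER_ACIDS:
        R.append(make_diffusion_reaction(TransportSpec(met, MC, BC, tr["g_met"])))
    R.append(make_diffusion_reaction(TransportSpec("CO2", BC, MC, tr["g_co2"])))
    R[-1].name = "CO2_LEAK"
    g_o2 = tr["g_co2"] * params["gas"]["o2_conductance_factor"]
    R.append(ReactionSpec(
        "O2_LEAK", {_k("O2", BCH): -1.0, _k("O2", MC): +1.0},
        RateLaw.DIFFUSION,
        {"g": g_o2, "source": _k("O2", BCH), "target": _k("O2", MC)}))
    return R


_ENZ_REACTIONS = {  # reaction -> enzyme switch controlling it
    "MDH_M": "MDH_M", "MDH_B": "MDH_B", "NADP_ME": "NADP_ME",
    "PEPCK": "PEPCK", "AspAT_M": "AspAT_M", "AspAT_B": "AspAT_B",
    "AlaAT_M": "AlaAT_M", "AlaAT_B": "AlaAT_B", "PPDK": "PPDK",
}


def _prune(reactions: list[ReactionSpec], caps: dict[str, float],
           catalog: dict[str, MetabolitePool],
           variant: Variant) -> tuple[list, list]:
    """Drop zero-capacity enzymes, then transports and pools left unused."""
    active: list[ReactionSpec] = []
    # The aspartate/PEPCK-only network carries no PGA/TP traffic at all:
    # aspartate brings no reducing power to the bundle sheath, the
    # chloroplast envelope exchanges only gases, the Calvin product leaves
    # as stromal starch, and the mesophyll keeps no Calvin-intermediate
    # metabolism (with no triose import, a mesophyll reduction/sucrose
    # branch would only drain the C4 carrier pool through the PGA/PEP
    # bridge).  This is the structural root of the pathway's LET
    # dependence: without PSII in the bundle sheath there is no NADPH
    # source for PGA reduction anywhere along its carbon path.
    drop = ({"PGA_ENV_B", "TP_ENV_B", "SUCROSE_SINK", "PGA_RED_M",
             "ENOLASE", "T_PGA_MC_CYT_BSC_CYT", "T_TP_MC_CYT_BSC_CYT"}
            if variant is Variant.ASP_PEPCK_ONLY else set())
    for r in reactions:
        if r.name in drop:
            continue
        switch = _ENZ_REACTIONS.get(r.name)
        if switch is not None and caps[switch] <= 0.0:
            continue
        active.append(r)

    # a transported species must take part in chemistry on at least one side
    chem_pools: set[str] = set()
    for r in active:
        if not r.name.startswith("T_"):
            chem_pools.update(r.stoichiometry)
            chem_pools.update(r.substrate_keys())
    kept: list[ReactionSpec] = []
    for r in active:
        if r.name.startswith("T_"):
            met = r.name.split("_")[1]
            if not any(pool_key(met, c) in chem_pools for c in
                       (MC, BC, MCH, BCH)):
                continue
        kept.append(r)

    used: set[str] = set()
    for r in kept:
        used.update(r.stoichiometry)
        used.update(r.substrate_keys())
    pools = [catalog[k] for k in catalog if k in used]
    return kept, pools


def build_variant(variant: Variant | str,
                  overrides: dict[str, float] | None = None,
                  params: dict | None = None
                  ) -> tuple[PathwayConfig, Network]:
    """Assemble one pathway variant as a (config, network) pair.

    ``overrides`` maps enzyme names to replacement Vmax values; overriding
    an enzyme the variant structurally lacks is a configuration error.
    """
    variant = Variant(variant)
    params = params if params is not None else load_params()
    caps, aspat_scale = _variant_caps(variant, params, overrides)
    catalog = _pool_catalog(params)
    reactions = _reaction_catalog(params, caps, aspat_scale)
    kept, pools = _prune(reactions, caps, catalog, variant)
    config = PathwayConfig(
        variant=variant, enzyme_caps=caps,
        asp_flux_target=params["pathway"]["asp_flux_target"],
        aspat_scale=aspat_scale)
    return config, Network(pools=pools, reactions=kept)


@dataclass
class C4Model:
    """A compiled pathway variant ready for simulation."""

    config: PathwayConfig
    network: Network
    params: dict
    compiled: CompiledNetwork = field(init=False)

    def __post_init__(self) -> None:
        vols = {Compartment(k): v for k, v in
                self.params["compartments"].items()}
        self.compiled = CompiledNetwork(self.network, vols)

    @property
    def variant(self) -> Variant:
        return self.config.variant


def build_model(variant: Variant | str,
                overrides: dict[str, float] | None = None,
                params: dict | None = None) -> C4Model:
    params = copy.deepcopy(params) if params is not None else load_params()
    config, network = build_variant(variant, overrides, params)
    return C4Model(config=config, network=network, params=params)


def asp_transfer_share(result) -> float | None:
    """Aspartate share of the forward C4-acid transfer at steady state.

    share = net ASP flux (MC -> BSC) / (net ASP + net MAL flux); None when
    the total forward transfer is not positive.
    """
    f_asp = result.fluxes.get("T_ASP_MC_CYT_BSC_CYT", 0.0)
    f_mal = result.fluxes.get("T_MAL_MC_CYT_BSC_CYT", 0.0)
    total = f_asp + f_mal
    if total <= 0:
        return None
    return f_asp / total


def calibrate_asp_share(variant: Variant | str,
                        target: float | None = None,
                        ppfd: float = 2000.0,
                        ci_ubar: float = 150.0,
                        tol: float = 0.02,
                        max_iter: int = 40,
                        params: dict | None = None) -> float:
    """Find the AspAT_M scale putting the aspartate transfer share on target.

    Deterministic bisection on a single multiplicative scale applied to the
    mesophyll aspartate aminotransferase capacity, evaluated at the
    reference condition (PPFD 2000, Ci 150 ubar).  The share grows
    monotonically with the scale, so a sign change brackets the root.
    Returns the calibrated scale; raises if the bracket does not contain
    the target.
    """
    from .steady_state import Drivers, run_to_steady_state  # lazy: avoid cycle

    variant = Variant(variant)
    if variant not in ASP_MAL_VARIANTS:
        raise ConfigurationError(
            "aspartate-share calibration applies to Asp+MAL variants only")
    params = copy.deepcopy(params) if params is not None else load_params()
    target = params["pathway"]["asp_flux_target"] if target is None else target
    if target == 0.0:
        return 0.0
    drivers = Drivers(ppfd=ppfd, ci_ubar=ci_ubar)

    def share_at(scale: float) -> float:
        params["pathway"]["aspat_scale"][variant.name] = scale
        model = build_model(variant, params=params)
        res = run_to_steady_state(model, drivers)
        s = asp_transfer_share(res)
        return -1.0 if s is None else s

    lo, hi = 0.0, 1.0
    s_hi = share_at(hi)
    while s_hi < target and hi < 64.0:
        lo, hi = hi, hi * 2.0
        s_hi = share_at(hi)
    if s_hi < target:
        raise ConfigurationError(
            f"aspartate share cannot reach {target} (max {s_hi:.3f})")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s = share_at(mid)
        if abs(s - target) < tol / 2.0:
            return mid
        if s < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
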