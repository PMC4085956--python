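"""Small synthetic reaction networks with closed-form steady states.

These toy networks exercise every piece of the ODE machinery — rate laws,
right-hand-side assembly, stiff integration, steady-state detection —
against exact analytic answers, without the full C4 model.  They are
deterministic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetic_core import (Compartment, MetabolitePool, Network, RateLaw,
                           ReactionSpec, pool_key)
from .transport import TransportSpec, make_diffusion_reaction

__all__ = ["ToyNetwork", "make_linear_chain", "make_shuttle_toy"]

_COMP = Compartment.MC_CYT


@dataclass
class ToyNetwork:
    network: Network
    volumes: dict[Compartment, float]
    closed_form: dict[str, float]     # pool key -> steady-state uM
    closed_form_fluxes: dict[str, float]


def make_linear_chain(n_pools: int, k_in: float, k_out: float,
                      volume: float = 1.0) -> ToyNetwork:
    """source -> M1 -> M2 -> ... -> Mn -> sink, first-order steps.

    Constant input k_in (umol m-2 s-1) and first-order consumption
    k_out * M_i at every step.  Flux continuity gives the closed form
    M_i* = k_in / k_out for every pool.
    """
    if n_pools < 1:
        raise ValueError("need at least one pool")
    if k_out <= 0 or k_in < 0:
        raise ValueError("rate constants must be positive (k_in >= 0)")
    pools = [MetabolitePool(f"M{i}", _COMP, concentration=1.0)
             for i in range(n_pools)]
    # constant source: irreversible MM on a clamped driver pool, Km -> 0
    driver = MetabolitePool("SRC", _COMP, concentration=1.0, clamped=True)
    reactions = [ReactionSpec(
        name="inflow",
        stoichiometry={pools[0].key: +1.0},
        rate_law=RateLaw.IRREV_MM_1S,
        params={"vmax": k_in, "substrates": [(driver.key, 1e-12)]},
        boundary=True,
    )]
    for i in range(n_pools):
        tgt = {} if i == n_pools - 1 else {pools[i + 1].key: +1.0}
        reactions.append(ReactionSpec(
            name=f"step{i}",
            stoichiometry={pools[i].key: -1.0, **tgt},
            rate_law=RateLaw.MASS_ACTION,
            params={"k": k_out, "keq": float("inf"),
                    "substrate": pools[i].key, "product": driver.key},
            boundary=(i == n_pools - 1),
        ))
    # first-order outflow expressed as k * (S - P/inf) = k * S
    ss = k_in / k_out
    closed = {p.key: ss for p in pools}
    fluxes = {r.name: k_in for r in reactions}
    return ToyNetwork(
        network=Network(pools=pools + [driver], reactions=reactions),
        volumes={_COMP: volume},
        closed_form=closed,
        closed_form_fluxes=fluxes,
    )


def make_shuttle_toy(flux: float = 10.0, g: float = 0.1,
                     volume: float = 1.0) -> ToyNetwork:
    """Two-compartment carrier loop mimicking the malate/pyruvate shuttle.

    A forward carrier F is produced at a constant rate in compartment A,
    diffuses to compartment B (conductance g), and is converted there to a
    return carrier R, which diffuses back and is reconverted.  At steady
    state each diffusive link carries ``flux``, so each gradient equals
    flux / g exactly; the conversions are made fast and first-order so the
    closed form stays simple.
    """
    a, b = Compartment.MC_CYT, Compartment.BSC_CYT
    k_conv = 50.0 * g   # fast conversion: gradients dominated by diffusion
    # carrier total chosen so the steady-state loop flux equals `flux`
    total = flux * (4.0 / k_conv + 2.0 / g)
    pools = [MetabolitePool(n, c, total / 4.0)
             for n, c in (("F", a), ("F", b), ("R", a), ("R", b))]
    fa, fb = pool_key("F", a), pool_key("F", b)
    ra, rb = pool_key("R", a), pool_key("R", b)
    reactions = [
        # A: R -> F driven to run at exactly `flux` in steady state
        ReactionSpec("convert_A", {ra: -1.0, fa: +1.0}, RateLaw.MASS_ACTION,
                     {"k": k_conv, "keq": float("inf"),
                      "substrate": ra, "product": fa}),
        ReactionSpec("convert_B", {fb: -1.0, rb: +1.0}, RateLaw.MASS_ACTION,
                     {"k": k_conv, "keq": float("inf"),
                      "substrate": fb, "product": rb}),
        make_diffusion_reaction(TransportSpec("F", a, b, g)),
        make_diffusion_reaction(TransportSpec("R", b, a, g)),
    ]
    # Conservation: the carrier total is invariant, so the steady state is
    # F_b = R_a = v/k_conv, F_a = F_b + v/g, R_b = R_a + v/g with
    # total = 4 v/k_conv + 2 v/g; `total` above was built to give v = flux.
    v = flux
    closed = {fb: v / k_conv, ra: v / k_conv,
              fa: v / k_conv + v / g, rb: v / k_conv + v / g}
    fluxes = {"convert_A": v, "convert_B": v,
              f"T_F_{a.value}_{b.value}": v, f"T_R_{b.value}_{a.value}": v}
    return ToyNetwork(
        network=Network(pools=pools, reactions=reactions),
        volumes={a: volume, b: volume},
        closed_form=closed,
        closed_form_fluxes=fluxes,
    )
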