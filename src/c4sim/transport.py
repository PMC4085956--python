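"""Intercellular and envelope transport, and the leakiness metric.

Metabolites move between the mesophyll and bundle-sheath cytosols by
diffusion through plasmodesmata: flux = g * (C_mc - C_bsc), with a single
conductance g_met shared by all transfer acids (overridable per species).
CO2 and O2 cross the bundle-sheath/mesophyll interface the same way, with
the O2 conductance scaled down by the solubility/diffusivity ratio.

Leakiness phi — the fraction of the PEPC carboxylation flux that escapes
the bundle sheath as CO2 instead of being fixed — is the standard
overcycling diagnostic: phi = v_leak / v_PEPC.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetic_core import Compartment, RateLaw, ReactionSpec, pool_key

__all__ = ["TransportSpec", "GradientRecord", "diffusive_flux", "leakiness",
           "make_diffusion_reaction"]

_GASES = ("CO2", "O2")


@dataclass
class TransportSpec:
    """One diffusive link between two compartments."""

    metabolite: str
    source: Compartment
    target: Compartment
    g: float                      # umol m-2 s-1 uM-1
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("conductance must be non-negative")


@dataclass
class GradientRecord:
    """Concentration gradient of one transfer metabolite at steady state."""

    metabolite: str
    c_mc: float                   # uM
    c_bsc: float                  # uM
    gradient: float               # c_mc - c_bsc, uM
    gradient_per_A: float | None  # uM per (umol m-2 s-1); None when A <= 0

    @classmethod
    def from_concentrations(cls, metabolite: str, c_mc: float, c_bsc: float,
                            a_net: float) -> "GradientRecord":
        grad = c_mc - c_bsc
        per_a = grad / a_net if a_net > 0 else None
        return cls(metabolite, c_mc, c_bsc, grad, per_a)


def diffusive_flux(spec: TransportSpec, c_from: float, c_to: float) -> float:
    """Diffusion down the gradient: g * (C_from - C_to), sign = direction."""
    if c_from < 0 or c_to < 0:
        raise ValueError("concentrations must be non-negative")
    flux = spec.g * (c_from - c_to)
    if not spec.bidirectional:
        flux = max(flux, 0.0)
    return flux


def leakiness(v_leak: float, v_pepc: float) -> float | None:
    """phi = v_leak / v_pepc; None (undefined) when v_pepc <= 0.

    At a productive steady state 0 <= phi < 1: the CO2 pump can leak at
    most what it imports.
    """
    if v_pepc <= 0:
        return None
    return v_leak / v_pepc


def make_diffusion_reaction(spec: TransportSpec) -> ReactionSpec:
    """Lower a :class:`TransportSpec` into a network reaction."""
    src = pool_key(spec.metabolite, spec.source)
    tgt = pool_key(spec.metabolite, spec.target)
    return ReactionSpec(
        name=f"T_{spec.metabolite}_{spec.source.value}_{spec.target.value}",
        stoichiometry={src: -1.0, tgt: +1.0},
        rate_law=RateLaw.DIFFUSION,
        params={"g": spec.g, "source": src, "target": tgt,
                "rectified": not spec.bidirectional},
    )
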