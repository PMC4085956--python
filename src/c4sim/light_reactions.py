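"""Electron transport and ATP/NADPH synthesis capacity per cell type.

Light absorbed by the leaf is split between mesophyll cells (MCs) and
bundle-sheath cells (BSCs) by the allocation fraction ``f_MC``.  In MCs all
electrons run through the linear chain (PSII + PSI), producing NADPH, ATP
and O2.  In BSCs an adjustable fraction ``LET_BSC`` (the u = v parameter)
of both light and electron-transport capacity runs through the linear
chain; the remainder drives PSI cyclic flow, which yields ATP only.

The electron transport rate J follows the non-rectangular hyperbola

    theta * J^2 - (I2 + Jmax) * J + I2 * Jmax = 0   (smaller root)

where I2 is the photon flux reaching PSII.  Linear flow needs two quanta
per electron (one at each photosystem), cyclic flow one quantum per
electron at PSI; the two chains also differ in proton economy, hence in
their ATP/e- yields (``eps_atp`` vs ``eps_atp_cyclic``).

The resulting ATP and NADPH synthesis capacities are Vmax = min(VmaxE,
eps * J), and O2 evolution is tied to linear flow: v_LET = J_l / 2 (one
NADPH per 2 e-) with half an O2 per turnover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LightParams",
    "EnergySupply",
    "nonrect_hyperbola",
    "bsc_let_split",
    "synthesis_caps",
    "o2_evolution",
    "energy_supply",
]


class ParameterError(ValueError):
    pass


@dataclass
class LightParams:
    """Light environment and per-cell electron-transport parameters.

    PPFD in umol photons m-2 s-1; Jmax in umol e- m-2 s-1; eps_* in
    ATP (NADPH) per electron; VmaxE_* are enzymatic synthesis caps in
    umol m-2 s-1.
    """

    ppfd: float
    f_mc: float = 0.65
    absorptance: float = 0.85
    beta_psii: float = 0.425
    jmax_m: float = 195.0
    jmax_b: float = 195.0
    theta: float = 0.7
    let_bsc: float = 0.25
    eps_atp: float = 0.75
    eps_atp_cyclic: float = 0.5
    eps_nadph: float = 0.5
    vmaxe_atp: float = 400.0
    vmaxe_nadph: float = 250.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_mc <= 1.0:
            raise ParameterError("f_mc must lie in [0, 1]")
        if not 0.0 < self.theta < 1.0:
            raise ParameterError("theta must lie in (0, 1)")
        if not 0.0 <= self.let_bsc <= 1.0:
            raise ParameterError("let_bsc must lie in [0, 1]")
        if self.jmax_m <= 0 or self.jmax_b <= 0:
            raise ParameterError("Jmax must be positive")
        if self.ppfd < 0:
            raise ParameterError("PPFD must be non-negative")


@dataclass
class EnergySupply:
    """Per-cell electron transport rates and synthesis capacities."""

    J_m: float
    J_b: float          # total BSC electron transport (linear + cyclic)
    J_l_b: float        # linear (LET) portion in BSCs
    Vmax_ATP_m: float
    Vmax_NADPH_m: float
    Vmax_ATP_b: float
    Vmax_NADPH_b: float
    v_O2_m: float       # O2 evolution credited to the MC chloroplast
    v_O2_b: float       # O2 evolution credited to the BSC chloroplast


def nonrect_hyperbola(i2: float, jmax: float, theta: float) -> float:
    """Smaller root of the non-rectangular hyperbola in J.

    Monotone non-decreasing in both I2 and Jmax, with J <= min(I2, Jmax).
    """
    if not 0.0 < theta < 1.0:
        raise ParameterError("theta must lie in (0, 1)")
    if jmax <= 0:
        raise ParameterError("Jmax must be positive")
    i2 = float(i2)
    if i2 < 0:
        raise ParameterError("I2 must be non-negative")
    if i2 == 0.0:
        return 0.0
    b = i2 + jmax
    disc = b * b - 4.0 * theta * i2 * jmax
    return (b - np.sqrt(disc)) / (2.0 * theta)


def bsc_let_split(params: LightParams, i_b: float) -> tuple[float, float]:
    """Split BSC light between linear and cyclic chains.

    ``i_b`` is the photosynthetically effective light absorbed by BSCs
    (umol photons m-2 s-1, spectral losses already applied).  The linear
    chain receives the fraction u = LET_BSC of it, with half the quanta
    exciting PSII (I_l_b = u * i_b / 2), against the capacity v * Jmax_b;
    u = v = 0 means no LET in BSCs at all.  The remainder drives PSI
    cyclic flow at one quantum per electron.  Returns (J_l_b, J_cyclic_b).
    """
    if i_b < 0:
        raise ParameterError("absorbed light must be non-negative")
    u = v = params.let_bsc
    j_l = 0.0
    if u > 0.0:
        i_l_b = 0.5 * u * i_b
        j_l = nonrect_hyperbola(i_l_b, v * params.jmax_b, params.theta)
    j_cyc = 0.0
    if u < 1.0:
        i1_cyc = (1.0 - u) * i_b
        j_cyc = nonrect_hyperbola(i1_cyc, (1.0 - v) * params.jmax_b,
                                  params.theta)
    return j_l, j_cyc


def synthesis_caps(params: LightParams, j_m: float, j_l_b: float,
                   j_b: float) -> EnergySupply:
    """ATP/NADPH synthesis capacities from the electron transport rates.

    Each synthesis reaction's effective Vmax is min(enzymatic cap,
    eps * J of the chain feeding it).  MCs run all electrons through the
    linear chain; in BSCs NADPH synthesis draws on the linear portion
    only, ATP synthesis on the whole of J_b (linear at eps_atp, cyclic at
    eps_atp_cyclic).
    """
    if min(j_m, j_l_b, j_b) < 0 or j_l_b > j_b + 1e-12:
        raise ParameterError("need 0 <= J_l_b <= J_b and J_m >= 0")
    j_cyc = j_b - j_l_b
    atp_m = min(params.vmaxe_atp, params.eps_atp * j_m)
    nadph_m = min(params.vmaxe_nadph, params.eps_nadph * j_m)
    atp_b = min(params.vmaxe_atp,
                params.eps_atp * j_l_b + params.eps_atp_cyclic * j_cyc)
    nadph_b = min(params.vmaxe_nadph, params.eps_nadph * j_l_b)
    return EnergySupply(
        J_m=j_m, J_b=j_b, J_l_b=j_l_b,
        Vmax_ATP_m=atp_m, Vmax_NADPH_m=nadph_m,
        Vmax_ATP_b=atp_b, Vmax_NADPH_b=nadph_b,
        v_O2_m=o2_evolution(j_m), v_O2_b=o2_evolution(j_l_b),
    )


def o2_evolution(j_l: float) -> float:
    """O2 evolution rate of a linear chain running at J_l (umol e- m-2 s-1).

    The water-splitting turnover H2O + NADP+ + 2 ADP -> NADPH + 2 ATP +
    1/2 O2 runs at v_LET = J_l / 2, so O2 evolves at v_LET / 2 = J_l / 4.
    """
    if j_l < 0:
        raise ParameterError("J_l must be non-negative")
    return 0.25 * j_l


def energy_supply(params: LightParams) -> EnergySupply:
    """Full pipeline: incident PPFD -> per-cell caps and O2 sources.

    Absorbed light I_m + I_b = absorptance * PPFD is split by f_MC; the
    spectral loss (2 * beta_psii, i.e. 0.85 by default) is applied before
    the chains, and the PSII halving is carried inside the I2 terms.
    """
    i_abs = params.absorptance * params.ppfd
    spectral = 2.0 * params.beta_psii
    i_m_eff = spectral * params.f_mc * i_abs
    i_b_eff = spectral * (1.0 - params.f_mc) * i_abs
    j_m = nonrect_hyperbola(0.5 * i_m_eff, params.jmax_m, params.theta)
    j_l_b, j_cyc = bsc_let_split(params, i_b_eff)
    return synthesis_caps(params, j_m, j_l_b, j_l_b + j_cyc)
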