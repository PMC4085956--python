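"""Core machinery of the two-cell C4 kinetic model.

The model is an ordinary-differential-equation system over metabolite pools
distributed across four compartments (mesophyll cytosol and chloroplast,
bundle-sheath cytosol and chloroplast).  Each pool obeys

    dM/dt = (sum of producing fluxes - sum of consuming fluxes) / V

with fluxes in umol m-2 s-1 (leaf-area basis), concentrations in uM and the
compartment volume V in L m-2, so that umol m-2 s-1 / (L m-2) = uM s-1.

This module knows nothing about photosynthesis: it defines pools, reaction
specifications with a small rate-law library, compiles a network into a fast
vectorized right-hand side, and audits stoichiometric bookkeeping (carbon,
amino groups, adenylate/pyridine pairing).  The C4 network itself is wired
in :mod:`c4sim.pathway_variants`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Compartment",
    "RateLaw",
    "MetabolitePool",
    "ReactionSpec",
    "ModelState",
    "Network",
    "CompiledNetwork",
    "ConfigurationError",
    "StateError",
    "rate",
    "build_rhs",
    "stoichiometric_audit",
    "pool_key",
    "CARBON_COUNT",
    "AMINO_COUNT",
]


class ConfigurationError(ValueError):
    """Raised for ill-formed networks or unknown rate-law kinds."""


class StateError(ValueError):
    """Raised when a state vector violates its invariants (e.g. negative)."""


class Compartment(str, enum.Enum):
    MC_CYT = "MC_CYT"
    MC_CHL = "MC_CHL"
    BSC_CYT = "BSC_CYT"
    BSC_CHL = "BSC_CHL"


class RateLaw(str, enum.Enum):
    IRREV_MM_1S = "irrev_mm_1s"
    IRREV_MM_2S = "irrev_mm_2s"
    IRREV_MM_3S = "irrev_mm_3s"
    REV_MM = "rev_mm"
    MASS_ACTION = "mass_action"
    RUBISCO_C = "rubisco_c"
    RUBISCO_O = "rubisco_o"
    DIFFUSION = "diffusion"
    LIGHT_SYNTHESIS = "light_synthesis"


#: carbon atoms per metabolite (used by the stoichiometric audit)
CARBON_COUNT = {
    "CO2": 1, "HCO3": 1, "O2": 0,
    "PEP": 3, "OAA": 4, "MAL": 4, "PYR": 3, "ASP": 4, "ALA": 3,
    "GLU": 5, "OG2": 5, "PGA": 3, "TP": 3, "RUBP": 5, "PGLY": 2,
    "ATP": 0, "ADP": 0, "NADPH": 0, "NADP": 0,
}

#: transferable amino groups per metabolite
AMINO_COUNT = {"ASP": 1, "ALA": 1, "GLU": 1}


def pool_key(name: str, compartment: Compartment | str) -> str:
    """Canonical pool identifier, e.g. ``"MAL@MC_CYT"``."""
    comp = Compartment(compartment)
    return f"{name}@{comp.value}"


def split_key(key: str) -> tuple[str, Compartment]:
    name, comp = key.split("@")
    return name, Compartment(comp)


@dataclass
class MetabolitePool:
    name: str
    compartment: Compartment
    concentration: float = 50.0     # uM
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise StateError(f"negative initial concentration for {self.key}")

    @property
    def key(self) -> str:
        return pool_key(self.name, self.compartment)


@dataclass
class ReactionSpec:
    """One enzymatic, transport or boundary step.

    ``stoichiometry`` maps pool keys to signed (possibly fractional)
    coefficients; ``params`` holds the rate-law constants.  Parameter keys
    by law kind:

    * irreversible MM: ``vmax`` and ``substrates`` = [(pool_key, Km), ...]
      (flux = Vmax * prod_i S_i/(S_i+Km_i); 1-3 substrates); optional
      ``inhibitors`` = [(pool_key, Ki), ...] multiply the flux by
      1/(1 + I/Ki) each (allosteric feedback, e.g. malate on PEPC)
    * REV_MM: ``vmax``, ``substrates``, ``products`` (same shape), ``keq``
      (concentration-basis, prod(P)/prod(S) at equilibrium)
    * MASS_ACTION: ``k``, ``substrate``, ``product``, ``keq``
      (flux = k * (S - P/Keq); the carbonic-anhydrase law)
    * RUBISCO_C / RUBISCO_O: ``vcmax``/``vomax``, ``kc``, ``ko`` (uM),
      ``km_rubp``, and pool keys ``co2``, ``o2``, ``rubp``
    * DIFFUSION: ``g``, ``source``, ``target``, optional ``rectified``
      (one-way carrier: flux = g * max(C_s - C_t, 0))
    * LIGHT_SYNTHESIS: ``vmax`` (the min(VmaxE, eps*J) cap, set at network
      build time), ``substrate``, ``km``
    """

    name: str
    stoichiometry: dict[str, float]
    rate_law: RateLaw
    params: dict
    active: bool = True
    boundary: bool = False   # carbon deliberately enters/leaves the system

    def substrate_keys(self) -> list[str]:
        p = self.params
        law = self.rate_law
        if law in (RateLaw.IRREV_MM_1S, RateLaw.IRREV_MM_2S, RateLaw.IRREV_MM_3S):
            return ([k for k, _ in p["substrates"]]
                    + [k for k, _ in p.get("inhibitors", [])])
        if law is RateLaw.REV_MM:
            return [k for k, _ in p["substrates"]] + [k for k, _ in p["products"]]
        if law is RateLaw.MASS_ACTION:
            return [p["substrate"], p["product"]]
        if law in (RateLaw.RUBISCO_C, RateLaw.RUBISCO_O):
            return [p["co2"], p["o2"], p["rubp"]]
        if law is RateLaw.DIFFUSION:
            return [p["source"], p["target"]]
        if law is RateLaw.LIGHT_SYNTHESIS:
            return [p["substrate"]]
        raise ConfigurationError(f"unknown rate law {law!r}")


@dataclass
class ModelState:
    """Concentration vector over the unclamped pools, with an index map."""

    values: np.ndarray
    index: dict[str, int]
    clamped: dict[str, float] = field(default_factory=dict)

    def get(self, key: str) -> float:
        if key in self.index:
            return float(self.values[self.index[key]])
        return self.clamped[key]

    def validate(self) -> None:
        if len(self.values) != len(self.index):
            raise StateError("state length does not match index map")
        if not np.all(np.isfinite(self.values)):
            raise StateError("non-finite concentration in state")
        if np.any(self.values < 0):
            raise StateError("negative concentration in state")


_IRREV_LAWS = (RateLaw.IRREV_MM_1S, RateLaw.IRREV_MM_2S, RateLaw.IRREV_MM_3S)


def _mm_sat(c: float, km: float) -> float:
    return c / (c + km)


def rate(reaction: ReactionSpec, state: ModelState) -> float:
    """Flux of a single reaction at a state, in umol m-2 s-1.

    Reference scalar implementation of the rate-law library; the compiled
    network (:class:`CompiledNetwork`) evaluates the same laws vectorized,
    and the test suite holds the two routes together.
    """
    if not reaction.active:
        raise ConfigurationError(f"reaction {reaction.name} is inactive")
    state.validate()
    p = reaction.params
    law = reaction.rate_law
    if law in _IRREV_LAWS:
        n_expected = {RateLaw.IRREV_MM_1S: 1, RateLaw.IRREV_MM_2S: 2,
                      RateLaw.IRREV_MM_3S: 3}[law]
        subs = p["substrates"]
        if len(subs) != n_expected:
            raise ConfigurationError(
                f"{reaction.name}: {law.value} needs {n_expected} substrates")
        v = p["vmax"]
        for key, km in subs:
            if km <= 0:
                raise ConfigurationError(f"{reaction.name}: Km must be > 0")
            v *= _mm_sat(state.get(key), km)
        for key, ki in p.get("inhibitors", []):
            v /= 1.0 + state.get(key) / ki
        return v
    if law is RateLaw.REV_MM:
        return _rev_mm_scalar(p, state)
    if law is RateLaw.MASS_ACTION:
        return p["k"] * (state.get(p["substrate"]) - state.get(p["product"]) / p["keq"])
    if law is RateLaw.RUBISCO_C:
        c, o, r = state.get(p["co2"]), state.get(p["o2"]), state.get(p["rubp"])
        return p["vcmax"] * c / (c + p["kc"] * (1.0 + o / p["ko"])) * _mm_sat(r, p["km_rubp"])
    if law is RateLaw.RUBISCO_O:
        c, o, r = state.get(p["co2"]), state.get(p["o2"]), state.get(p["rubp"])
        return p["vomax"] * o / (o + p["ko"] * (1.0 + c / p["kc"])) * _mm_sat(r, p["km_rubp"])
    if law is RateLaw.DIFFUSION:
        flux = p["g"] * (state.get(p["source"]) - state.get(p["target"]))
        if p.get("rectified", False):
            flux = max(flux, 0.0)
        return flux
    if law is RateLaw.LIGHT_SYNTHESIS:
        return p["vmax"] * _mm_sat(state.get(p["substrate"]), p["km"])
    raise ConfigurationError(f"unknown rate law {law!r}")


def _rev_mm_scalar(p: dict, state: ModelState) -> float:
    """Compact reversible Michaelis-Menten (Haldane-consistent).

    v = Vmax * (prod S/KmS - prod P/KmP / Keq') /
        (prod (1+S/KmS) + prod (1+P/KmP) - 1)

    with Keq' = Keq * prod KmS / prod KmP so that the flux vanishes exactly
    at prod P / prod S = Keq and its sign follows the displacement.  The
    Haldane-implied reverse capacity is Vmax / Keq'.
    """
    num_f, den_f = 1.0, 1.0
    for key, km in p["substrates"]:
        r = state.get(key) / km
        num_f *= r
        den_f *= 1.0 + r
    num_r, den_r = 1.0, 1.0
    kms = np.prod([km for _, km in p["substrates"]])
    kmp = np.prod([km for _, km in p["products"]])
    for key, km in p["products"]:
        r = state.get(key) / km
        num_r *= r
        den_r *= 1.0 + r
    keq_scaled = p["keq"] * kms / kmp
    return p["vmax"] * (num_f - num_r / keq_scaled) / (den_f + den_r - 1.0)


@dataclass
class Network:
    """A set of pools and reactions, ready for compilation."""

    pools: list[MetabolitePool]
    reactions: list[ReactionSpec]

    def __post_init__(self) -> None:
        keys = [p.key for p in self.pools]
        if len(set(keys)) != len(keys):
            raise ConfigurationError("duplicate pool keys")

    def pool(self, key: str) -> MetabolitePool:
        for p in self.pools:
            if p.key == key:
                return p
        raise KeyError(key)

    def active_reactions(self) -> list[ReactionSpec]:
        return [r for r in self.reactions if r.active]

    def initial_state(self) -> ModelState:
        unclamped = [p for p in self.pools if not p.clamped]
        index = {p.key: i for i, p in enumerate(unclamped)}
        clamped = {p.key: p.concentration for p in self.pools if p.clamped}
        values = np.array([p.concentration for p in unclamped], dtype=float)
        return ModelState(values=values, index=index, clamped=clamped)


class CompiledNetwork:
    """Vectorized ODE right-hand side for a :class:`Network`.

    Compiles the reaction list into index/parameter arrays grouped by
    rate-law kind, so one RHS evaluation is a handful of numpy operations
    regardless of network size.  Concentrations are clipped at zero inside
    the RHS (the stiff solver may probe slightly negative values); the
    public :func:`rate` rejects negative states instead.
    """

    def __init__(self, network: Network, volumes: dict[Compartment, float]):
        self.network = network
        for comp, vol in volumes.items():
            if vol <= 0:
                raise ConfigurationError(f"volume of {comp} must be > 0")
        self.volumes = {Compartment(k): float(v) for k, v in volumes.items()}

        reactions = network.active_reactions()
        self.reactions = reactions
        self.reaction_index = {r.name: i for i, r in enumerate(reactions)}

        unclamped = [p for p in network.pools if not p.clamped]
        clamped = [p for p in network.pools if p.clamped]
        self.pool_index = {p.key: i for i, p in enumerate(unclamped)}
        self._n_unclamped = len(unclamped)
        # extended concentration vector: unclamped | clamped | [1.0, 0.0]
        self._clamped_vals = np.array([p.concentration for p in clamped])
        self._ext_index = dict(self.pool_index)
        for j, p in enumerate(clamped):
            self._ext_index[p.key] = self._n_unclamped + j
        self._one_slot = self._n_unclamped + len(clamped)
        self._zero_slot = self._one_slot + 1

        self._check_wiring(reactions, unclamped)
        self._build_arrays(reactions, unclamped)

    # -- construction -----------------------------------------------------

    def _check_wiring(self, reactions, unclamped) -> None:
        known = set(self._ext_index)
        referenced: set[str] = set()
        for r in reactions:
            for key in list(r.stoichiometry) + r.substrate_keys():
                if key not in known:
                    raise ConfigurationError(
                        f"reaction {r.name} references undeclared pool {key}")
            referenced.update(r.stoichiometry)
        orphans = [p.key for p in unclamped if p.key not in referenced]
        if orphans:
            raise ConfigurationError(f"orphan pools (no reactions): {orphans}")

    def _build_arrays(self, reactions, unclamped) -> None:
        nr = len(reactions)
        ext = self._ext_index
        one, zero = self._one_slot, self._zero_slot

        # stoichiometry (unclamped rows only) and volume scaling
        N = np.zeros((self._n_unclamped, nr))
        for j, r in enumerate(reactions):
            for key, coeff in r.stoichiometry.items():
                i = self.pool_index.get(key)
                if i is not None:
                    N[i, j] = coeff
        self._N = N
        inv_vol = np.array(
            [1.0 / self.volumes[p.compartment] for p in unclamped])
        self._inv_vol = inv_vol

        # group rows
        def rows(pred):
            return [j for j, r in enumerate(reactions) if pred(r)]

        self._g_irrev = rows(lambda r: r.rate_law in _IRREV_LAWS
                             or r.rate_law is RateLaw.LIGHT_SYNTHESIS)
        self._g_rev = rows(lambda r: r.rate_law is RateLaw.REV_MM)
        self._g_ma = rows(lambda r: r.rate_law is RateLaw.MASS_ACTION)
        self._g_diff = rows(lambda r: r.rate_law is RateLaw.DIFFUSION)
        self._g_rub = rows(lambda r: r.rate_law in
                           (RateLaw.RUBISCO_C, RateLaw.RUBISCO_O))

        # irreversible MM / light synthesis: pad to 3 substrates + 3 inhibitors
        if self._g_irrev:
            n = len(self._g_irrev)
            idx = np.full((n, 3), one)
            km = np.zeros((n, 3))   # km = 0 sentinel -> saturation factor 1
            i_idx = np.full((n, 3), zero)  # zero-concentration slot
            i_ki = np.ones((n, 3))
            vmax = np.zeros(n)
            for a, j in enumerate(self._g_irrev):
                r = reactions[j]
                if r.rate_law is RateLaw.LIGHT_SYNTHESIS:
                    subs = [(r.params["substrate"], r.params["km"])]
                else:
                    subs = r.params["substrates"]
                vmax[a] = r.params["vmax"]
                for b, (key, k) in enumerate(subs):
                    if k <= 0:
                        raise ConfigurationError(
                            f"{r.name}: Km must be > 0")
                    idx[a, b] = ext[key]
                    km[a, b] = k
                for b, (key, k) in enumerate(r.params.get("inhibitors", [])):
                    i_idx[a, b] = ext[key]
                    i_ki[a, b] = k
            self._irrev_idx, self._irrev_km, self._irrev_vmax = idx, km, vmax
            self._irrev_i_idx, self._irrev_i_ki = i_idx, i_ki

        # reversible MM: pad substrates/products to 3 each
        if self._g_rev:
            n = len(self._g_rev)
            s_idx = np.full((n, 3), one); s_km = np.ones((n, 3))
            p_idx = np.full((n, 3), one); p_km = np.ones((n, 3))
            s_pad = np.zeros((n, 3), dtype=bool); p_pad = np.zeros((n, 3), dtype=bool)
            vmax = np.zeros(n); keq_s = np.zeros(n)
            for a, j in enumerate(self._g_rev):
                r = reactions[j]
                subs, prods = r.params["substrates"], r.params["products"]
                vmax[a] = r.params["vmax"]
                kms = np.prod([k for _, k in subs])
                kmp = np.prod([k for _, k in prods])
                keq_s[a] = r.params["keq"] * kms / kmp
                for b, (key, k) in enumerate(subs):
                    s_idx[a, b], s_km[a, b] = ext[key], k
                for b in range(len(subs), 3):
                    s_pad[a, b] = True
                for b, (key, k) in enumerate(prods):
                    p_idx[a, b], p_km[a, b] = ext[key], k
                for b in range(len(prods), 3):
                    p_pad[a, b] = True
            self._rev = (s_idx, s_km, s_pad, p_idx, p_km, p_pad, vmax, keq_s)

        if self._g_ma:
            self._ma_k = np.array([reactions[j].params["k"] for j in self._g_ma])
            self._ma_keq = np.array([reactions[j].params["keq"] for j in self._g_ma])
            self._ma_s = np.array([ext[reactions[j].params["substrate"]] for j in self._g_ma])
            self._ma_p = np.array([ext[reactions[j].params["product"]] for j in self._g_ma])

        if self._g_diff:
            self._d_g = np.array([reactions[j].params["g"] for j in self._g_diff])
            self._d_s = np.array([ext[reactions[j].params["source"]] for j in self._g_diff])
            self._d_t = np.array([ext[reactions[j].params["target"]] for j in self._g_diff])
            self._d_rect = np.array(
                [bool(reactions[j].params.get("rectified", False)) for j in self._g_diff])

        self._rub_specs = [(j, reactions[j]) for j in self._g_rub]
        self._nr = nr

    # -- runtime updates ----------------------------------------------------

    def set_vmax(self, name: str, vmax: float) -> None:
        """Update the Vmax of a reaction in place (used for the per-run
        light-driven synthesis caps and light-activation of enzymes)."""
        if vmax < 0:
            raise ConfigurationError("Vmax must be >= 0")
        j = self.reaction_index[name]
        if j in self._g_irrev:
            self._irrev_vmax[self._g_irrev.index(j)] = vmax
        elif j in self._g_rev:
            self._rev[6][self._g_rev.index(j)] = vmax
        else:
            raise ConfigurationError(
                f"{name} does not carry a Vmax (law "
                f"{self.reactions[j].rate_law.value})")
        self.reactions[j].params["vmax"] = vmax

    def set_clamped(self, key: str, value: float) -> None:
        """Update a clamped pool's boundary concentration (uM)."""
        if value < 0:
            raise StateError("clamped concentration must be >= 0")
        i = self._ext_index[key] - self._n_unclamped
        if i < 0 or i >= len(self._clamped_vals):
            raise ConfigurationError(f"{key} is not a clamped pool")
        self._clamped_vals[i] = value
        self.network.pool(key).concentration = value

    # -- evaluation -------------------------------------------------------

    def _extended(self, y: np.ndarray) -> np.ndarray:
        c = np.maximum(y, 0.0)
        return np.concatenate([c, self._clamped_vals, [1.0, 0.0]])

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        """Flux of every active reaction (umol m-2 s-1) at state ``y``."""
        c = self._extended(np.asarray(y, dtype=float))
        v = np.zeros(self._nr)
        if self._g_irrev:
            s = c[self._irrev_idx]
            sat = np.where(self._irrev_km > 0, s / (s + self._irrev_km), 1.0)
            inh = 1.0 + c[self._irrev_i_idx] / self._irrev_i_ki
            v[self._g_irrev] = (self._irrev_vmax * sat.prod(axis=1)
                                / inh.prod(axis=1))
        if self._g_rev:
            s_idx, s_km, s_pad, p_idx, p_km, p_pad, vmax, keq_s = self._rev
            rs = np.where(s_pad, 1.0, c[s_idx] / s_km)
            rp = np.where(p_pad, 1.0, c[p_idx] / p_km)
            ds = np.where(s_pad, 1.0, 1.0 + c[s_idx] / s_km)
            dp = np.where(p_pad, 1.0, 1.0 + c[p_idx] / p_km)
            num = rs.prod(axis=1) - rp.prod(axis=1) / keq_s
            den = ds.prod(axis=1) + dp.prod(axis=1) - 1.0
            v[self._g_rev] = vmax * num / den
        if self._g_ma:
            v[self._g_ma] = self._ma_k * (c[self._ma_s] - c[self._ma_p] / self._ma_keq)
        if self._g_diff:
            f = self._d_g * (c[self._d_s] - c[self._d_t])
            v[self._g_diff] = np.where(self._d_rect, np.maximum(f, 0.0), f)
        for j, r in self._rub_specs:
            p = r.params
            co2 = c[self._ext_index[p["co2"]]]
            o2 = c[self._ext_index[p["o2"]]]
            rubp = c[self._ext_index[p["rubp"]]]
            f_rubp = rubp / (rubp + p["km_rubp"])
            if r.rate_law is RateLaw.RUBISCO_C:
                v[j] = p["vcmax"] * co2 / (co2 + p["kc"] * (1.0 + o2 / p["ko"])) * f_rubp
            else:
                v[j] = p["vomax"] * o2 / (o2 + p["ko"] * (1.0 + co2 / p["kc"])) * f_rubp
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """dC/dt in uM s-1 over the unclamped pools (clamped pools are
        held constant by construction; they are not in the state)."""
        return (self._N @ self.fluxes(y)) * self._inv_vol

    def flux_balance(self, y: np.ndarray) -> np.ndarray:
        """Net areal flux into each unclamped pool (umol m-2 s-1)."""
        return self._N @ self.fluxes(y)

    def state(self, y: np.ndarray) -> ModelState:
        clamped = {k: self._clamped_vals[i - self._n_unclamped]
                   for k, i in self._ext_index.items() if i >= self._n_unclamped}
        return ModelState(values=np.asarray(y, dtype=float),
                          index=dict(self.pool_index), clamped=clamped)


def build_rhs(reactions: list[ReactionSpec],
              pools: list[MetabolitePool],
              volumes: dict[Compartment, float]):
    """Assemble the mass-balance ODE right-hand side.

    Returns ``(rhs, compiled)`` where ``rhs(t, y)`` gives dC/dt (uM s-1)
    over the unclamped pools and ``compiled`` is the underlying
    :class:`CompiledNetwork` (flux evaluation, index maps).
    """
    net = Network(pools=pools, reactions=reactions)
    compiled = CompiledNetwork(net, volumes)
    return compiled.rhs, compiled


# -- stoichiometric audit -------------------------------------------------

@dataclass
class AuditReport:
    carbon_balance: dict[str, float]     # reaction -> net carbon created
    amino_balance: dict[str, float]
    adenylate_balance: dict[str, float]  # ATP+ADP coefficient sum
    pyridine_balance: dict[str, float]   # NADPH+NADP coefficient sum
    flagged: list[str]
    moieties: dict[str, list[str]]

    @property
    def ok(self) -> bool:
        return not self.flagged


def stoichiometric_audit(reactions: list[ReactionSpec],
                         tol: float = 1e-9) -> AuditReport:
    """Check elemental and moiety bookkeeping of every active reaction.

    Boundary reactions (declared carbon import/export, e.g. the sucrose
    sink) are reported but not flagged.  Everything else must conserve
    carbon and transferable amino groups exactly, and must change ATP and
    ADP (NADPH and NADP) by equal and opposite amounts.
    """
    carbon, amino, aden, pyr = {}, {}, {}, {}
    flagged: list[str] = []
    moieties: dict[str, list[str]] = {}
    for r in reactions:
        if not r.active:
            continue
        dc = da = 0.0
        for key, coeff in r.stoichiometry.items():
            name, _ = split_key(key)
            dc += coeff * CARBON_COUNT.get(name, 0)
            da += coeff * AMINO_COUNT.get(name, 0)
        dat = sum(c for k, c in r.stoichiometry.items()
                  if split_key(k)[0] in ("ATP", "ADP"))
        dpy = sum(c for k, c in r.stoichiometry.items()
                  if split_key(k)[0] in ("NADPH", "NADP"))
        carbon[r.name], amino[r.name] = dc, da
        aden[r.name], pyr[r.name] = dat, dpy
        if not r.boundary and (abs(dc) > tol or abs(da) > tol):
            flagged.append(r.name)
        if abs(dat) > tol or abs(dpy) > tol:
            flagged.append(r.name)
        for key in r.stoichiometry:
            name, comp = split_key(key)
            if name in ("NADPH", "NADP"):
                moieties.setdefault(f"NADPH+NADP@{comp.value}", [])
                if r.name not in moieties[f"NADPH+NADP@{comp.value}"]:
                    moieties[f"NADPH+NADP@{comp.value}"].append(r.name)
            if name in ("ATP", "ADP"):
                moieties.setdefault(f"ATP+ADP@{comp.value}", [])
                if r.name not in moieties[f"ATP+ADP@{comp.value}"]:
                    moieties[f"ATP+ADP@{comp.value}"].append(r.name)
            if name in ("GLU", "OG2"):
                cell = "MC" if comp in (Compartment.MC_CYT, Compartment.MC_CHL) else "BSC"
                moieties.setdefault(f"GLU+OG2@{cell}", [])
                if r.name not in moieties[f"GLU+OG2@{cell}"]:
                    moieties[f"GLU+OG2@{cell}"].append(r.name)
    return AuditReport(carbon_balance=carbon, amino_balance=amino,
                       adenylate_balance=aden, pyridine_balance=pyr,
                       flagged=sorted(set(flagged)), moieties=moieties)
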