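"""Driver scans reproducing the study's simulation experiments.

Each scan runs one steady state per grid point per variant and tabulates
net assimilation, leakiness, photorespiration, bundle-sheath CO2, pools
and gradients.  Every point is computed by the same deterministic
induction protocol (light ramp, see :func:`c4sim.steady_state
.run_to_steady_state`), so scans are reproducible bit-for-bit; points
that fail the convergence criterion are flagged in the table, never
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway_variants import C4Model, Variant, build_model
from .steady_state import Drivers, SteadyStateResult, run_to_steady_state

__all__ = ["ScanSpec", "light_response_scan", "allocation_scan",
           "pepc_sensitivity", "gradient_snapshot", "argmax_f_mc",
           "crossover", "standard_dominance_threshold",
           "DEFAULT_LET_SET", "PPFD_GRID", "F_MC_GRID"]

#: bundle-sheath LET fractions scanned in the allocation experiment
DEFAULT_LET_SET = (0.0, 0.25, 0.5, 1.0)
#: light-response grid (umol m-2 s-1)
PPFD_GRID = tuple(range(0, 2501, 50))
#: mesophyll allocation grid
F_MC_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 3))


@dataclass
class ScanSpec:
    """A validated scan request (used by the CLI)."""

    scan_variable: str
    grid: tuple
    variants: tuple[Variant, ...]
    drivers: Drivers
    let_bsc: float | None = None

    def __post_init__(self) -> None:
        if self.scan_variable not in ("PPFD", "f_MC", "LET_BSC", "PEPC_scale"):
            raise ValueError(f"unknown scan variable {self.scan_variable!r}")
        g = list(self.grid)
        if len(g) < 3 or any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("grid must be strictly increasing with >= 3 points")


def _row(variant: Variant, r: SteadyStateResult) -> dict:
    row = {"variant": variant.value, **r.to_row()}
    return row


def light_response_scan(variants=None, ci_ubar: float = 150.0,
                        ppfd_grid=PPFD_GRID, let_bsc: float | None = None,
                        f_mc: float | None = None) -> pd.DataFrame:
    """A-PPFD response for each variant (plus phi, v_pr, pools, BSC CO2).

    Steady states are continued along the grid (warm start from the last
    productive point), which follows the physiological induction branch.
    """
    variants = [Variant(v) for v in (variants or list(Variant))]
    rows = []
    for variant in variants:
        model = build_model(variant)
        y = None
        for ppfd in ppfd_grid:
            r = run_to_steady_state(model, Drivers(ppfd=float(ppfd),
                                                   ci_ubar=ci_ubar),
                                    y0=y, let_bsc=let_bsc, f_mc=f_mc,
                                    ramp=(y is None))
            if r.A > 0:
                y = r.state.values
            rows.append(_row(variant, r))
    df = pd.DataFrame(rows)
    best = df.loc[df.groupby("ppfd")["A"].idxmax(), ["ppfd", "variant"]]
    df = df.merge(best.rename(columns={"variant": "best_variant"}), on="ppfd")
    return df


def standard_dominance_threshold(df: pd.DataFrame,
                                 reference: Variant = Variant.NADP_ME_STANDARD
                                 ) -> tuple[float, float]:
    """PPFD above which the reference variant never again has the highest
    A — the upper end of its dominance region on the light response,
    reported as (midpoint, width) of the bracketing grid interval.

    The threshold is taken from the *last* grid point where the reference
    is strictly maximal: near the light-compensation point the curves lie
    within fractions of a unit of each other and may graze, which says
    nothing about the capacity crossover this threshold measures.  NaN
    when the reference is nowhere strictly maximal or never overtaken.
    """
    ref = reference.value
    piv = df.pivot_table(index="ppfd", columns="variant", values="A")
    others = [c for c in piv.columns if c != ref]
    strict = (piv[ref] > piv[others].max(axis=1)) & (piv[ref] > 0)
    if not strict.any():
        return float("nan"), float("nan")
    last = float(piv.index[strict][-1])
    above = piv.index[piv.index > last]
    if len(above) == 0:
        return float("nan"), float("nan")
    nxt = float(above[0])
    return 0.5 * (last + nxt), nxt - last


def allocation_scan(variants=None, ppfd: float = 300.0, ci_ubar: float = 150.0,
                    f_grid=F_MC_GRID, let_values=DEFAULT_LET_SET
                    ) -> pd.DataFrame:
    """A(f_MC) for each variant and bundle-sheath LET fraction."""
    variants = [Variant(v) for v in (variants or list(Variant))]
    if max(np.diff(f_grid)) > 0.05 + 1e-9:
        raise ValueError("allocation grid step must be <= 0.05")
    rows = []
    for variant in variants:
        model = build_model(variant)
        for let in let_values:
            for f in f_grid:
                r = run_to_steady_state(model, Drivers(ppfd=ppfd,
                                                       ci_ubar=ci_ubar),
                                        f_mc=float(f), let_bsc=float(let))
                rows.append(_row(variant, r))
    return pd.DataFrame(rows)


def argmax_f_mc(df: pd.DataFrame, variant: Variant | str,
                let_bsc: float) -> tuple[float, bool]:
    """Optimal mesophyll allocation for one (variant, LET) curve.

    Ties (within 1e-9 of the maximum) are broken toward the lower f_MC
    and flagged: returns (f_mc_opt, tie_flag).
    """
    sub = df[(df["variant"] == Variant(variant).value)
             & (np.isclose(df["let_bsc"], let_bsc))].sort_values("f_mc")
    a = sub["A"].to_numpy()
    f = sub["f_mc"].to_numpy()
    imax = int(np.argmax(a))
    ties = np.isclose(a, a[imax], atol=1e-9)
    return float(f[np.argmax(ties)]), int(ties.sum()) > 1


def crossover(df: pd.DataFrame, variant_a: Variant | str,
              variant_b: Variant | str, let_bsc: float,
              x: str = "f_mc", direction: str = "down") -> tuple[float, float]:
    """Value of ``x`` where A(variant_a) - A(variant_b) changes sign.

    ``direction`` selects which sign change defines the crossover when the
    curves graze each other more than once: "down" reports the highest
    grid interval where the difference turns from positive to negative
    (variant_a dominant *below* the crossover), "up" the highest interval
    where it turns from negative to positive (dominant *above*).  Reported
    as the midpoint of the bracketing interval with its width; NaN when
    the difference never changes sign that way.  Points where both
    variants are unproductive (A <= 0) are ignored.
    """
    a = df[(df["variant"] == Variant(variant_a).value)
           & (np.isclose(df["let_bsc"], let_bsc))].sort_values(x)
    b = df[(df["variant"] == Variant(variant_b).value)
           & (np.isclose(df["let_bsc"], let_bsc))].sort_values(x)
    xs = a[x].to_numpy()
    diff = a["A"].to_numpy() - b["A"].to_numpy()
    keep = (a["A"].to_numpy() > 0) | (b["A"].to_numpy() > 0)
    xs, diff = xs[keep], diff[keep]
    sign = np.sign(diff)
    step = np.diff(sign)
    want = step < 0 if direction == "down" else step > 0
    flips = np.nonzero(want)[0]
    if len(flips) == 0:
        return float("nan"), float("nan")
    i = int(flips[-1])
    return 0.5 * (xs[i] + xs[i + 1]), xs[i + 1] - xs[i]


def pepc_sensitivity(variant: Variant | str = Variant.ASP_MAL_PEPCK_ME,
                     ppfd: float = 2000.0, ci_ubar: float = 150.0,
                     scales=(0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0)
                     ) -> pd.DataFrame:
    """Leakiness and assimilation response to reduced PEPC capacity.

    Reports relative changes versus the unscaled enzyme: a 15% activity
    reduction should trim leakiness by a few percent at little cost in A.
    """
    variant = Variant(variant)
    scales = tuple(scales)
    if 1.0 not in scales or 0.85 not in scales:
        raise ValueError("scale grid must include 1.0 and 0.85")
    base_params = build_model(variant).params
    vmax0 = base_params["enzymes"]["PEPC"]["vmax"]
    rows = []
    for s in sorted(scales):
        model = build_model(variant, overrides={"PEPC": vmax0 * s})
        r = run_to_steady_state(model, Drivers(ppfd=ppfd, ci_ubar=ci_ubar))
        rows.append({"scale": s, **_row(variant, r)})
    df = pd.DataFrame(rows)
    ref = df.loc[np.isclose(df["scale"], 1.0)].iloc[0]
    df["dphi_rel"] = (df["phi"] - ref["phi"]) / ref["phi"]
    df["dA_rel"] = (df["A"] - ref["A"]) / ref["A"]
    return df


def gradient_snapshot(variants=None, ppfd: float = 2000.0,
                      ci_ubar: float = 150.0) -> pd.DataFrame:
    """Per-metabolite MC/BSC gradients, normalized by A, plus pool totals."""
    variants = [Variant(v) for v in (variants or list(Variant))]
    rows = []
    for variant in variants:
        model = build_model(variant)
        r = run_to_steady_state(model, Drivers(ppfd=ppfd, ci_ubar=ci_ubar))
        for g in r.gradients:
            rows.append({
                "variant": variant.value, "metabolite": g.metabolite,
                "c_mc": g.c_mc, "c_bsc": g.c_bsc, "gradient": g.gradient,
                "gradient_per_A": (np.nan if g.gradient_per_A is None
                                   else g.gradient_per_A),
                "pool_total": r.pools.get(g.metabolite, np.nan),
                "A": r.A, "converged": r.converged,
            })
    return pd.DataFrame(rows)
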