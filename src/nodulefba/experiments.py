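"""The in-silico experiment suite over the nodule holobiont.

Each experiment is a reproducible scenario scan emitting a tidy table
(:class:`ScanResult`): ammonium titrations, Pareto curves over fixation
efficiency and nodulation fraction, nodulation optimisation, the four-scenario
cost decomposition of symbiotic nitrogen fixation, the zone III
carbon-source-switch titration, the peribacteroid proton-access contrast and
the carbon-substrate growth screen.

Conventions: growth is shoot+root biomass production reported in
g day^-1 (g plant DW)^-1 inside scan tables (h^-1 values times 24);
"fixation efficiency" e is nitrogenase flux per gram nodule dry weight, so
the per-plant nitrogenase flux is e * f at nodulation fraction f.  Infeasible
scan points are recorded with growth 0 and their solver status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model

from nodulefba.assembly import (
    HolobiontModel,
    HolobiontSpec,
    NODULE_PLANT_ZONES,
    _attach_objective,
    build_holobiont,
    fix_fixation_efficiency,
    set_nitrogen_source,
    set_nodulation_inplace,
)
from nodulefba.engine import FluxSolution, optimize, optimize_growth

HOURS_PER_DAY = 24.0
C_MASS = 12.011
N_MASS = 14.007
GROWTH_EPS = 1e-6

TRACKED_FLUXES = {
    "nitrogenase": "BacteroidIII_NITROGENASE",
    "bacteroid_sucrose_uptake": "T_NoduleIII__PBS_III__sucr",
    "bacteroid_dicarboxylate_uptake": (
        "T_NoduleIII__PBS_III__succ",
        "T_NoduleIII__PBS_III__mal",
        "T_NoduleIII__PBS_III__fum",
    ),
    "bacteroid_oxidase": "BacteroidIII_OXIDASE",
}


@dataclass
class ScanResult:
    scenario: str
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CostDecomposition:
    """Relative growth of the four scenarios and the derived cost shares.

    Ratios are normalised to the non-nodulated ammonium-fed maximum (= 1).
    Shares partition the growth gap (1 - r1): direct fixation energy,
    nodule/bacteroid maintenance, and nodule/bacteroid synthesis.
    """

    growth: dict[str, float]
    ratios: tuple[float, float, float, float]
    shares: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "growth_per_day": self.growth,
            "ratios": {
                "fixing_nodulated": self.ratios[0],
                "fixing_no_maintenance": self.ratios[1],
                "fixing_non_nodulated": self.ratios[2],
                "ammonium_non_nodulated": self.ratios[3],
            },
            "shares": self.shares,
        }


def cost_shares_from_ratios(r1: float, r2: float, r3: float) -> dict[str, float]:
    """Partition the SNF growth gap from the three relative growth rates.

    fixation_energy = (1 - r3) / (1 - r1); maintenance = (r2 - r1) / (1 - r1);
    synthesis = (r3 - r2) / (1 - r1).  The three shares sum to one.
    """
    gap = 1.0 - r1
    return {
        "fixation_energy": (1.0 - r3) / gap,
        "maintenance": (r2 - r1) / gap,
        "synthesis": (r3 - r2) / gap,
    }


# ---------------------------------------------------------------------------
# headline metrics


def nodule_co2_export(holo: HolobiontModel, fluxes: pd.Series) -> float:
    total = 0.0
    for zone in ["NoduleI", *NODULE_PLANT_ZONES]:
        total += max(float(fluxes.get(f"{zone}_EX_co2", 0.0)), 0.0)
    return total


def carbon_cost_per_nitrogen(holo: HolobiontModel, fluxes: pd.Series) -> float:
    """Nodule CO2 export per N2 fixed, in g C (g N)^-1."""
    n2 = float(fluxes.get("BacteroidIII_NITROGENASE", 0.0))
    if n2 <= GROWTH_EPS:
        return math.nan
    co2 = nodule_co2_export(holo, fluxes)
    return (co2 * C_MASS) / (2.0 * n2 * N_MASS)


def reference_metrics(holo: HolobiontModel) -> dict[str, float]:
    """Default-scenario headline numbers (parsimonious flux routing)."""
    sol = optimize_growth(holo, parsimonious=True)
    if not sol.optimal:
        raise RuntimeError("default holobiont scenario is infeasible")
    f = holo.spec.nodulation_fraction
    bact_dw = f * holo.spec.bacteroid_fraction_of_nodule
    dicarb = sum(
        float(sol.fluxes.get(rid, 0.0))
        for rid in TRACKED_FLUXES["bacteroid_dicarboxylate_uptake"]
    )
    return {
        "plant_growth_per_day": sol.objective_value * HOURS_PER_DAY,
        "fixation_umol_h": float(sol.fluxes.get("BacteroidIII_NITROGENASE", 0.0)),
        "carbon_cost_gC_per_gN": carbon_cost_per_nitrogen(holo, sol.fluxes),
        "dicarboxylate_uptake_umol_h_per_g_bacteroid": dicarb / bact_dw,
    }


# ---------------------------------------------------------------------------
# scan helpers


def _record(
    holo: HolobiontModel, sol: FluxSolution, point: dict, tracked: bool
) -> dict:
    point = dict(point)
    point["growth_per_day"] = (
        sol.objective_value * HOURS_PER_DAY if sol.optimal else 0.0
    )
    point["status"] = sol.status
    if tracked:
        for key, rid in TRACKED_FLUXES.items():
            if isinstance(rid, tuple):
                val = sum(float(sol.fluxes.get(r, 0.0)) for r in rid) if sol.optimal else 0.0
            else:
                val = float(sol.fluxes.get(rid, 0.0)) if sol.optimal else 0.0
            point[key] = val
        point["nodule_co2_export"] = (
            nodule_co2_export(holo, sol.fluxes) if sol.optimal else 0.0
        )
    return point


def _golden_section_max(fun, lo: float, hi: float, tol: float = 1e-4):
    """Maximise a unimodal scalar function on [lo, hi]; returns (x*, f(x*))."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    xs = [(a, fun(a)), (c, fc), (d, fd), (b, fun(b))]
    return max(xs, key=lambda t: t[1])


# ---------------------------------------------------------------------------
# experiments


def ammonium_titration(
    holo: HolobiontModel,
    mode: str = "vary_efficiency",
    nh4_grid=None,
    efficiency: float = 150.0,
    f_max: float = 0.25,
) -> ScanResult:
    """Plant growth versus root ammonium availability.

    ``vary_efficiency``: nodulation stays at the spec default while nitrogenase
    flux is free.  ``vary_nodulation``: fixation efficiency is pinned at
    *efficiency* (umol h^-1 g nodule^-1) and the nodulation fraction is
    optimised per point by golden-section search.
    """
    if nh4_grid is None:
        nh4_grid = np.arange(0.0, 51.0, 1.0)
    if mode not in ("vary_efficiency", "vary_nodulation"):
        raise ValueError(f"unknown titration mode {mode!r}")
    work = holo.copy()
    rows = []
    for cap in nh4_grid:
        if mode == "vary_efficiency":
            set_nitrogen_source(work, "ammonium", nh4_cap=float(cap))
            sol = optimize_growth(work)
            rows.append(_record(work, sol, {"nh4_cap": float(cap)}, tracked=False))
        else:
            set_nitrogen_source(work, "ammonium", nh4_cap=float(cap))

            def growth_at(f: float) -> float:
                set_nodulation_inplace(work, f)
                fix_fixation_efficiency(work, efficiency, f=f)
                s = optimize_growth(work)
                return s.objective_value if s.optimal else 0.0

            f_opt, g_opt = _golden_section_max(growth_at, 0.0, f_max)
            rows.append(
                {
                    "nh4_cap": float(cap),
                    "growth_per_day": g_opt * HOURS_PER_DAY,
                    "status": "optimal" if g_opt > 0 else "zero",
                    "f_opt": f_opt,
                }
            )
    return ScanResult(f"ammonium_titration[{mode}]", pd.DataFrame(rows))


def pareto_fixation(
    holo: HolobiontModel,
    efficiency_grid=None,
    zone3_o2_cap: str = "default",
    tracked: bool = False,
) -> ScanResult:
    """Growth versus pinned N2-fixation efficiency at constant nodulation."""
    if efficiency_grid is None:
        efficiency_grid = np.arange(0.0, 601.0, 10.0)
    work = holo.copy()
    if zone3_o2_cap == "none":
        work.model.reactions.get_by_id("NoduleIII_EX_o2").lower_bound = -1000.0
    elif zone3_o2_cap != "default":
        raise ValueError("zone3_o2_cap must be 'default' or 'none'")
    rows = []
    for e in efficiency_grid:
        fix_fixation_efficiency(work, float(e))
        sol = optimize_growth(work, parsimonious=tracked)
        rows.append(_record(work, sol, {"efficiency": float(e)}, tracked))
    return ScanResult(f"pareto_fixation[o2={zone3_o2_cap}]", pd.DataFrame(rows))


def pareto_nodulation(
    holo: HolobiontModel, f_grid=None, efficiency: float = 150.0
) -> ScanResult:
    """Growth versus nodulation fraction at constant fixation efficiency."""
    if f_grid is None:
        f_grid = np.arange(0.0, 0.2501, 0.005)
    work = holo.copy()
    rows = []
    for f in f_grid:
        set_nodulation_inplace(work, float(f))
        fix_fixation_efficiency(work, efficiency, f=float(f))
        sol = optimize_growth(work)
        rows.append(_record(work, sol, {"f": float(f)}, tracked=False))
    return ScanResult("pareto_nodulation", pd.DataFrame(rows))


def optimize_nodulation_curve(
    holo: HolobiontModel,
    efficiency_grid=None,
    f_cap: float | None = None,
    zone3_o2_cap: str = "default",
    f_tol: float = 1e-4,
) -> ScanResult:
    """Growth versus efficiency with nodulation optimised per point.

    ``f_cap`` bounds the allowed nodule biomass fraction (None = uncapped,
    i.e. up to 40%).  The inner 1-D maximisation uses golden-section search
    (the LP optimum is piecewise-linear concave in f).
    """
    if efficiency_grid is None:
        efficiency_grid = np.arange(25.0, 601.0, 25.0)
    cap = 0.4 if f_cap is None else f_cap
    work = holo.copy()
    if zone3_o2_cap == "none":
        work.model.reactions.get_by_id("NoduleIII_EX_o2").lower_bound = -1000.0
    rows = []
    for e in efficiency_grid:

        def growth_at(f: float) -> float:
            set_nodulation_inplace(work, f)
            fix_fixation_efficiency(work, float(e), f=f)
            s = optimize_growth(work)
            return s.objective_value if s.optimal else 0.0

        f_opt, g_opt = _golden_section_max(growth_at, 0.0, cap, tol=f_tol)
        rows.append(
            {
                "efficiency": float(e),
                "growth_per_day": g_opt * HOURS_PER_DAY,
                "f_opt": f_opt,
                "status": "optimal" if g_opt > 0 else "zero",
            }
        )
    return ScanResult(f"optimize_nodulation[f_cap={f_cap}]", pd.DataFrame(rows))


def _zero_nodule_maintenance(holo: HolobiontModel) -> None:
    for tissue in holo.spec.maintenance:
        if tissue in ("Shoot", "Root"):
            continue
        for suffix in ("ATPM", "NGAM"):
            rid = f"{tissue}_{suffix}"
            if holo.model.reactions.has_id(rid):
                holo.model.reactions.get_by_id(rid).lower_bound = 0.0


def cost_decomposition(holo: HolobiontModel) -> CostDecomposition:
    """Four-scenario decomposition of the metabolic cost of SNF.

    (1) default N2-only; (2) N2-only without nodule/bacteroid maintenance;
    (3) N2-only, non-nodulated (no nodule biomass in the objective, no nodule
    maintenance) but still fixing; (4) non-nodulated with unlimited exogenous
    ammonium.  Ratios are growths relative to (4).
    """
    r = holo.spec.shoot_root_ratio
    shoot_root = {"Shoot": r / (1 + r), "Root": 1 / (1 + r)}

    def solve(modify) -> float:
        work = holo.copy()
        modify(work)
        sol = optimize_growth(work)
        if not sol.optimal:
            raise RuntimeError("cost-decomposition scenario infeasible")
        return sol.objective_value

    g1 = solve(lambda w: None)
    g2 = solve(_zero_nodule_maintenance)

    def non_nodulated(w: HolobiontModel) -> None:
        _attach_objective(w, shoot_root)
        w.objective_terms = dict(shoot_root)
        _zero_nodule_maintenance(w)

    g3 = solve(non_nodulated)

    def ammonium(w: HolobiontModel) -> None:
        non_nodulated(w)
        set_nitrogen_source(w, "ammonium")

    g4 = solve(ammonium)
    ratios = (g1 / g4, g2 / g4, g3 / g4, 1.0)
    shares = cost_shares_from_ratios(*ratios[:3])
    growth = {
        "fixing_nodulated": g1 * HOURS_PER_DAY,
        "fixing_no_maintenance": g2 * HOURS_PER_DAY,
        "fixing_non_nodulated": g3 * HOURS_PER_DAY,
        "ammonium_non_nodulated": g4 * HOURS_PER_DAY,
    }
    return CostDecomposition(growth=growth, ratios=ratios, shares=shares)


def carbon_switch_scan(
    holo_sucrose_variant: HolobiontModel, oxidase_cap_grid=None
) -> ScanResult:
    """Zone III carbon-source use versus a mitochondrial-oxidase ceiling.

    Requires a holobiont built with ``spec.sucrose_bacteroid_variant`` (zone
    III bacteroids may import sucrose).  The overall zone III O2 cap is
    lifted; instead the plant mitochondrial terminal oxidase of zone III is
    capped at each grid value.  Parsimonious solutions are reported so the
    sucrose/dicarboxylate split is reproducible.
    """
    if not holo_sucrose_variant.spec.sucrose_bacteroid_variant:
        raise ValueError("carbon_switch_scan needs the sucrose-bacteroid variant")
    if oxidase_cap_grid is None:
        oxidase_cap_grid = np.concatenate([[1000.0], np.geomspace(100.0, 0.01, 20)])
    work = holo_sucrose_variant.copy()
    work.model.reactions.get_by_id("NoduleIII_EX_o2").lower_bound = -1000.0
    mto = work.model.reactions.get_by_id("NoduleIII_MTO")
    rows = []
    for cap in oxidase_cap_grid:
        mto.upper_bound = float(cap)
        sol = optimize_growth(work, parsimonious=True)
        rows.append(_record(work, sol, {"oxidase_cap": float(cap)}, tracked=True))
    table = pd.DataFrame(rows).sort_values("oxidase_cap", ignore_index=True)
    return ScanResult("carbon_switch", table)


def proton_access_test(
    plant: Model,
    bacterium: Model,
    spec: HolobiontSpec | None = None,
    calls=None,
    nitrogen: str = "n2",
) -> dict[str, float]:
    """Growth with and without bacteroid access to peribacteroid protons.

    Two builds differing only in ``bacteroid_proton_access``.  With a
    dicarboxylate-only zone III carbon whitelist the access-off build cannot
    feed its bacteroids, so under N2-only nitrogen growth is zero (the forced
    bacteroid maintenance actually renders the model infeasible).
    """
    from dataclasses import replace

    spec = spec or HolobiontSpec()
    out = {}
    for label, access in (("access_on", True), ("access_off", False)):
        s = replace(spec, bacteroid_proton_access=access)
        holo = build_holobiont(plant, bacterium, s, calls, nitrogen=nitrogen)
        sol = optimize_growth(holo)
        out[label] = sol.objective_value * HOURS_PER_DAY if sol.optimal else 0.0
        out[f"{label}_status"] = sol.status
    return out


def substrate_screen(
    model: Model,
    substrate_list: list[str] | None = None,
    basal_medium: dict[str, float] | None = None,
    uptake_rate: float = 10.0,
) -> pd.DataFrame:
    """Growth/no-growth call per carbon substrate on a basal medium.

    Substrates are base metabolite names (an exchange ``EX_<name>`` must
    exist, otherwise the substrate is recorded ``untestable``).  The basal
    medium closes every carbon exchange and keeps O2/NH3/salts open.
    """
    carbon = ["succ", "mal", "fum", "glc", "sucr", "triose", "xyl"]
    if substrate_list is None:
        substrate_list = carbon
    rows = []
    with model:
        for base in carbon:
            rid = f"EX_{base}"
            if model.reactions.has_id(rid):
                model.reactions.get_by_id(rid).lower_bound = 0.0
        for rid, lb in (basal_medium or {}).items():
            model.reactions.get_by_id(rid).lower_bound = lb
        for base in substrate_list:
            rid = f"EX_{base}"
            if not model.reactions.has_id(rid):
                rows.append({"substrate": base, "call": "untestable", "growth": 0.0})
                continue
            with model:
                model.reactions.get_by_id(rid).lower_bound = -uptake_rate
                sol = optimize(model)
            growth = sol.objective_value if sol.optimal else 0.0
            rows.append(
                {
                    "substrate": base,
                    "call": "growth" if growth > GROWTH_EPS else "no-growth",
                    "growth": growth,
                }
            )
    return pd.DataFrame(rows)
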