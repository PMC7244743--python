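"""LP-backed simulation primitives: FBA, FVA, deletions, scans, classification.

Optimisation is delegated to cobrapy/optlang over GLPK.  Degenerate optima:
objective values are unique (and solver-order independent within tolerance)
but flux vectors are not, so whenever a specific flux route is reported a
parsimonious solution (minimal total |v| at >= 99.99% of the optimum) is used;
plain FBA is kept for objective-value questions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model

from nodulefba.assembly import HolobiontModel, plant_growth

FLUX_ZERO = 1e-9
COMPARE_TOL = 1e-6
PFBA_FRACTION = 0.9999
CENTRAL_GROWTH_DROP = 0.10


def _cobra_model(model: Model | HolobiontModel) -> Model:
    return model.model if isinstance(model, HolobiontModel) else model


@dataclass
class FluxSolution:
    """Objective value (g biomass h^-1 gDW^-1), flux vector, solver status."""

    objective_value: float
    fluxes: pd.Series
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    ranges: pd.DataFrame  # index reaction id, columns minimum / maximum
    fraction: float = 0.99

    def range(self, rid: str) -> tuple[float, float]:
        row = self.ranges.loc[rid]
        return float(row["minimum"]), float(row["maximum"])


@dataclass
class RobustnessCurve:
    reaction_id: str
    flux_values: np.ndarray
    objective_values: np.ndarray


@dataclass
class ReactionClass:
    reaction_id: str
    zone: str
    reaction_class: str  # inactive | active | central
    growth_without: float = float("nan")


def optimize(model: Model | HolobiontModel, parsimonious: bool = False) -> FluxSolution:
    """FBA: maximise the model objective subject to Sv = 0 and bounds.

    Infeasible/unbounded problems are reported in ``status`` (objective 0.0),
    never raised.
    """
    import warnings

    m = _cobra_model(model)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return _optimize_inner(m, parsimonious)
    except Exception:  # noqa: BLE001 - solver-level infeasibility
        return FluxSolution(0.0, pd.Series(dtype=float), "infeasible")


def _optimize_inner(m: Model, parsimonious: bool) -> FluxSolution:
    try:
        if parsimonious:
            from cobra.flux_analysis import pfba

            sol = pfba(m, fraction_of_optimum=PFBA_FRACTION)
            # pfba's own objective is the |v| sum; recompute the real one
            value = float(
                sum(sol.fluxes[r.id] * c for r, c in _objective_coefs(m).items())
            )
            return FluxSolution(value, sol.fluxes, "optimal")
        sol = m.optimize()
    except Exception:  # noqa: BLE001 - solver-level infeasibility
        return FluxSolution(0.0, pd.Series(dtype=float), "infeasible")
    if sol.status != "optimal" or sol.objective_value is None:
        return FluxSolution(0.0, pd.Series(dtype=float), sol.status)
    return FluxSolution(float(sol.objective_value), sol.fluxes, "optimal")


def _objective_coefs(model: Model):
    return {r: r.objective_coefficient for r in model.reactions if r.objective_coefficient}


def optimize_growth(holo: HolobiontModel, parsimonious: bool = False) -> FluxSolution:
    """FBA reporting shoot+root plant growth as the objective value."""
    sol = optimize(holo, parsimonious=parsimonious)
    if sol.optimal:
        sol.objective_value = plant_growth(holo, sol.objective_value)
    return sol


def fva(
    model: Model | HolobiontModel,
    fraction: float = 0.99,
    reaction_subset: list[str] | None = None,
) -> FVAResult:
    """Per-reaction flux min/max with objective >= fraction x optimum."""
    from cobra.flux_analysis import flux_variability_analysis

    m = _cobra_model(model)
    base = m.slim_optimize(error_value=None)
    if base is None:
        raise RuntimeError("FVA requires a feasible base solution")
    ranges = flux_variability_analysis(
        m,
        reaction_list=reaction_subset,
        fraction_of_optimum=fraction,
        loopless=None,
    )
    return FVAResult(ranges=ranges, fraction=fraction)


def delete_gene(
    holo: HolobiontModel,
    gene: str | tuple[str, str],
    scope: str = "global",
) -> FluxSolution:
    """Re-solve with a gene (or gene pair) deleted.

    ``scope="global"`` removes every tissue copy of the base gene id
    simultaneously; a tissue tag as scope deletes only that tissue's copy.
    Reactions whose gene rule evaluates false are closed before solving.
    """
    genes = [gene] if isinstance(gene, str) else list(gene)
    targets: list[str] = []
    model = holo.model
    for g in genes:
        if model.genes.has_id(g):  # already a prefixed copy
            copies = [g]
        elif scope == "global":
            copies = holo.base_gene_copies(g)
        else:
            copies = [f"{scope}_{g}"] if model.genes.has_id(f"{scope}_{g}") else []
        if not copies:
            raise KeyError(f"gene {g!r} not found (scope {scope})")
        targets.extend(copies)
    with model:
        for gid in targets:
            model.genes.get_by_id(gid).knock_out()
        sol = optimize_growth(holo)
    return sol


def remove_reaction(
    holo: HolobiontModel, reaction: str, zone: str | None = None
) -> FluxSolution:
    """Re-solve with one reaction closed in one zone copy only."""
    rid = reaction if zone is None else f"{zone}_{reaction}"
    model = holo.model
    if not model.reactions.has_id(rid):
        raise KeyError(f"reaction {rid} not in model")
    with model:
        model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        sol = optimize_growth(holo)
    return sol


def robustness_scan(
    model: Model | HolobiontModel,
    reaction: str,
    n_points: int = 21,
    growth_floor: float = 1e-9,
) -> RobustnessCurve:
    """Objective as a function of one reaction's (fixed) flux.

    Phase 1 brackets the interval of flux values with nonzero objective:
    starting from the FVA feasibility range, each endpoint is refined by
    bisection (tolerance 1e-4 x range width) against the predicate "objective
    > growth_floor when flux is fixed here".  Phase 2 fixes the flux at
    ``n_points`` evenly spaced values across the bracket and records the
    maximised objective.
    """
    m = _cobra_model(model)

    def value_at(v: float) -> float:
        with m:
            m.reactions.get_by_id(reaction).bounds = (v, v)
            out = m.slim_optimize(error_value=None)
        return float(out) if out is not None else 0.0

    span = fva(m, fraction=0.0, reaction_subset=[reaction]).range(reaction)
    lo, hi = span
    if abs(hi - lo) < FLUX_ZERO:
        return RobustnessCurve(reaction, np.array([lo]), np.array([value_at(lo)]))
    # find any interior point with growth, then bisect both edges
    grid0 = np.linspace(lo, hi, 11)
    vals0 = np.array([value_at(v) for v in grid0])
    alive = np.where(vals0 > growth_floor)[0]
    if alive.size == 0:
        return RobustnessCurve(reaction, grid0, vals0)
    tol = 1e-4 * (hi - lo)

    def bisect(outside: float, inside: float) -> float:
        while abs(inside - outside) > tol:
            mid = 0.5 * (inside + outside)
            if value_at(mid) > growth_floor:
                inside = mid
            else:
                outside = mid
        return inside

    left = grid0[alive[0]]
    right = grid0[alive[-1]]
    if alive[0] > 0:
        left = bisect(grid0[alive[0] - 1], left)
    elif value_at(lo) > growth_floor:
        left = lo
    if alive[-1] < len(grid0) - 1:
        right = bisect(grid0[alive[-1] + 1], right)
    elif value_at(hi) > growth_floor:
        right = hi
    xs = np.linspace(left, right, n_points)
    ys = np.array([value_at(v) for v in xs])
    return RobustnessCurve(reaction, xs, ys)


def classify_reactions(
    holo: HolobiontModel,
    zone: str,
    fva_fraction: float = 0.99,
    reaction_subset: list[str] | None = None,
) -> list[ReactionClass]:
    """Classify a zone's reactions as inactive / active / central.

    inactive: the FVA range at >= 99% optimum is {0}; active otherwise;
    central: active and removing the reaction (in this zone only) cuts plant
    growth by more than 10% versus the full model.  For
    ``zone="differentiation"`` a base reaction is central only if it is
    central in each of IId, IIp and IZ.
    """
    if zone == "differentiation":
        return _classify_differentiation(holo, fva_fraction)
    if zone not in holo.tissue_index:
        raise KeyError(f"unknown zone {zone!r}")
    rids = sorted(reaction_subset or holo.tissue_index[zone]["reactions"])
    rids = [r for r in rids if holo.model.reactions.has_id(r)]
    full = optimize_growth(holo)
    if not full.optimal:
        raise RuntimeError("classification requires a feasible model")
    ranges = fva(holo, fraction=fva_fraction, reaction_subset=rids)
    out = []
    for rid in rids:
        vmin, vmax = ranges.range(rid)
        if abs(vmin) < FLUX_ZERO and abs(vmax) < FLUX_ZERO:
            out.append(ReactionClass(rid, zone, "inactive"))
            continue
        without = remove_reaction(holo, rid).objective_value
        central = without < (1 - CENTRAL_GROWTH_DROP) * full.objective_value
        out.append(
            ReactionClass(rid, zone, "central" if central else "active", without)
        )
    return out


def _classify_differentiation(holo: HolobiontModel, fva_fraction: float):
    zones = [z for z in holo.tissue_index if z.endswith(("IId", "IIp", "IZ"))]
    per_zone = {z: classify_reactions(holo, z, fva_fraction) for z in zones}
    by_base: dict[str, list[ReactionClass]] = {}
    for z, classes in per_zone.items():
        for rc in classes:
            base = rc.reaction_id[len(z) + 1 :]
            by_base.setdefault(base, []).append(rc)
    out = []
    for base, classes in sorted(by_base.items()):
        labels = {rc.reaction_class for rc in classes}
        if labels == {"inactive"}:
            label = "inactive"
        elif all(rc.reaction_class == "central" for rc in classes) and len(
            classes
        ) == len(zones):
            label = "central"
        else:
            label = "active"
        out.append(ReactionClass(base, "differentiation", label))
    return out


def mass_balance_residuals(model: Model | HolobiontModel, fluxes: pd.Series) -> float:
    """Max |S v| over metabolites; optimal solutions satisfy this <= 1e-6."""
    m = _cobra_model(model)
    worst = 0.0
    acc: dict[str, float] = {}
    for rxn in m.reactions:
        v = float(fluxes.get(rxn.id, 0.0))
        if v == 0.0:
            continue
        for met, coef in rxn.metabolites.items():
            acc[met.id] = acc.get(met.id, 0.0) + coef * v
    for total in acc.values():
        worst = max(worst, abs(total))
    return worst
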