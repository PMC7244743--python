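"""Assembly of the multi-tissue nodulated-plant holobiont model.

The integration procedure: replicate the plant model into seven tissues
(shoot, root, five nodule developmental zones I / IId / IIp / IZ / III),
embed a replicated bacterium ("bacteroid") inside a peribacteroid-space (PBS)
compartment in each of the four infected zones, connect the tissues with
directed transport reactions (single-metabolite diffusion steps pay an ATP
cost in the source tissue), gate each zone's reaction space with expression
calls, attach the composite biomass objective, apply the physiological
constraint set (uptake caps, forced maintenance, the zone III carbon
whitelist), and prune dead ends.

All identifiers are namespaced with ``<TissueTag>_`` prefixes; peribacteroid
metabolites live in ``PBS_<zone>`` compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from cobra import Metabolite, Model, Reaction
from cobra.manipulation import rename_genes

from nodulefba.core import remove_dead_ends
from nodulefba.gating import gate_zone
from nodulefba.toy import (
    BACTEROID_ZONES,
    C4_DICARBOXYLATES,
    NODULE_ZONE_NAMES,
    PLANT_ZONES,
    SPECIES,
    ExpressionCallSet,
)

TISSUE_TAGS = PLANT_ZONES + BACTEROID_ZONES
NODULE_PLANT_ZONES = ["NoduleIId", "NoduleIIp", "NoduleIZ", "NoduleIII"]

OBJECTIVE_ID = "BIOMASS_OVERALL"

#: Reference composite-objective weights at the default 2% nodulation.
DEFAULT_ZONE_WEIGHTS = {
    "I": 0.00100,
    "IId_plant": 0.00675,
    "IId_bact": 0.00225,
    "IIp_plant": 0.00675,
    "IIp_bact": 0.00225,
    "IZ_plant": 0.00075,
    "IZ_bact": 0.00025,
}

#: objective-weight key -> biomass-producing tissue tag
_WEIGHT_TISSUE = {
    "Shoot": "Shoot",
    "Root": "Root",
    "I": "NoduleI",
    "IId_plant": "NoduleIId",
    "IId_bact": "BacteroidIId",
    "IIp_plant": "NoduleIIp",
    "IIp_bact": "BacteroidIIp",
    "IZ_plant": "NoduleIZ",
    "IZ_bact": "BacteroidIZ",
}


@dataclass(frozen=True)
class HolobiontSpec:
    """All assembly parameters.

    Maintenance rates are umol ATP h^-1 (g plant DW)^-1 (the nmol-scale
    nodule-zone rates are written in umol); uptake caps in umol h^-1 gDW^-1.
    """

    nodulation_fraction: float = 0.02
    shoot_root_ratio: float = 2.0
    zone_biomass_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_WEIGHTS)
    )
    bacteroid_fraction_of_nodule: float = 0.25
    transport_atp_cost: float = 0.25
    maintenance: dict[str, float] = field(
        default_factory=lambda: {
            "Shoot": 74.0,
            "Root": 37.0,
            "NoduleI": 0.111,
            "NoduleIId": 0.750,
            "NoduleIIp": 0.750,
            "NoduleIZ": 0.083,
            "NoduleIII": 0.833,
            "BacteroidIId": 5.7,
            "BacteroidIIp": 5.7,
            "BacteroidIZ": 0.6,
            "BacteroidIII": 6.3,
        }
    )
    light_cap: float = 1000.0
    co2_cap: float = 1000.0
    zone3_o2_cap: float = 8.9847
    zone3_carbon_whitelist: tuple[str, ...] = C4_DICARBOXYLATES
    zone3_carbon_cap: float = 1000.0
    bacteroid_proton_access: bool = True
    sucrose_bacteroid_variant: bool = False
    proton_per_pump_atp: float = 2.0

    def __post_init__(self):
        if not 0 <= self.nodulation_fraction < 1:
            raise ValueError("nodulation_fraction must be in [0, 1)")
        if any(v < 0 for v in self.maintenance.values()):
            raise ValueError("maintenance rates must be non-negative")


@dataclass
class TransportRow:
    """(metabolite, from-tissue, to-tissue, reversible?, atp_cost?)."""

    metabolite: str
    source: str
    target: str
    reversible: bool = False
    atp_cost: bool = False


def default_transport_table(spec: HolobiontSpec) -> list[TransportRow]:
    """Inter-tissue links: sucrose shoot->root->zones, nitrogen back up.

    Ammonium links are reversible so that fixed nitrogen can travel zone III
    -> root -> shoot while differentiation zones can draw root nitrogen for
    their own (and their bacteroids') biomass.
    """
    rows = [TransportRow("sucr", "Shoot", "Root", atp_cost=True)]
    for zone in ["NoduleI", *NODULE_PLANT_ZONES]:
        rows.append(TransportRow("sucr", "Root", zone, atp_cost=True))
    rows.append(TransportRow("nh4", "Root", "Shoot", reversible=True))
    for zone in ["NoduleI", *NODULE_PLANT_ZONES]:
        rows.append(TransportRow("nh4", "Root", zone, reversible=True))
    return rows


@dataclass
class HolobiontModel:
    """The integrated model plus provenance maps."""

    model: Model
    tissue_index: dict[str, dict[str, set[str]]]
    link_reactions: list[str]
    objective_terms: dict[str, float]
    spec: HolobiontSpec

    def copy(self) -> "HolobiontModel":
        return HolobiontModel(
            model=self.model.copy(),
            tissue_index={
                t: {k: set(v) for k, v in entry.items()}
                for t, entry in self.tissue_index.items()
            },
            link_reactions=list(self.link_reactions),
            objective_terms=dict(self.objective_terms),
            spec=self.spec,
        )

    def tissue_reactions(self, tag: str) -> set[str]:
        return self.tissue_index[tag]["reactions"]

    def tissue_genes(self, tag: str) -> set[str]:
        return self.tissue_index[tag]["genes"]

    def base_gene_copies(self, base_gene: str) -> list[str]:
        """All tissue copies ``<Tag>_<base_gene>`` present in the model."""
        copies = []
        for tag in self.tissue_index:
            gid = f"{tag}_{base_gene}"
            if gid in self.tissue_index[tag]["genes"]:
                copies.append(gid)
        return copies


# ---------------------------------------------------------------------------
# replication and linking


def replicate_tissue(model: Model, tag: str) -> Model:
    """Deep copy with every metabolite/reaction/gene/compartment id prefixed."""
    if tag not in TISSUE_TAGS:
        raise ValueError(f"unregistered tissue tag {tag!r}")
    prefix = f"{tag}_"
    if any(m.id.startswith(prefix) for m in model.metabolites):
        raise ValueError(f"model already carries the {prefix} prefix")
    rep = model.copy()
    rep.id = f"{tag}_{model.id}"
    if rep.genes:
        rename_genes(rep, {g.id: f"{prefix}{g.id}" for g in rep.genes})
    for met in rep.metabolites:
        met.id = f"{prefix}{met.id}"
        met.compartment = f"{prefix}{met.compartment}"
    for rxn in rep.reactions:
        rxn.id = f"{prefix}{rxn.id}"
    rep.repair()
    return rep


def _merge(holo: Model, replica: Model) -> None:
    holo.add_reactions(list(replica.reactions))


def _hydrolysis_terms(tag: str, amount: float) -> dict[str, float]:
    return {
        f"{tag}_atp_c": -amount,
        f"{tag}_h2o_c": -amount,
        f"{tag}_adp_c": amount,
        f"{tag}_pi_c": amount,
        f"{tag}_h_c": amount,
    }


def link_tissues(
    holo: HolobiontModel, transport_table: list[TransportRow]
) -> HolobiontModel:
    """Add one inter-tissue transport reaction per table row.

    Rows flagged ``atp_cost`` additionally hydrolyse ``spec.transport_atp_cost``
    ATP in the source tissue (the energetic cost of single-metabolite
    diffusion between compartments).
    """
    model = holo.model
    cost = holo.spec.transport_atp_cost
    for row in transport_table:
        src = f"{row.source}_{row.metabolite}_c"
        dst = f"{row.target}_{row.metabolite}_c"
        for mid, tissue in ((src, row.source), (dst, row.target)):
            if not model.metabolites.has_id(mid):
                raise KeyError(f"metabolite {row.metabolite} missing in {tissue}")
        rid = f"T_{row.source}__{row.target}__{row.metabolite}"
        rxn = Reaction(
            rid,
            name=f"{row.metabolite} transport {row.source}->{row.target}",
            lower_bound=-1000.0 if row.reversible else 0.0,
            upper_bound=1000.0,
        )
        rxn.subsystem = "inter-tissue transport"
        model.add_reactions([rxn])
        stoich = {model.metabolites.get_by_id(src): -1.0,
                  model.metabolites.get_by_id(dst): 1.0}
        rxn.add_metabolites(stoich)
        if row.atp_cost and cost:
            rxn.add_metabolites(
                {
                    model.metabolites.get_by_id(mid): coef
                    for mid, coef in _hydrolysis_terms(row.source, cost).items()
                }
            )
        holo.link_reactions.append(rid)
    return holo


def embed_bacteroid(
    holo: HolobiontModel,
    bacterium: Model,
    zone: str,
    proton_access: bool | None = None,
) -> HolobiontModel:
    """Embed a bacteroid copy of *bacterium* in nodule zone *zone*.

    The bacterium's boundary compartment becomes the peribacteroid space
    ``PBS_<zone>``; its environment exchanges are replaced by plant<->PBS
    transfer reactions (carbon per the zone whitelist, gases/ammonia/alanine
    freely) plus an ATP-driven plant proton pump that acidifies the PBS.  The
    bacteroid's dicarboxylate H+-symporters can only run when the pump exists
    (``proton_access``); without it the PBS holds no protons.
    """
    if zone not in NODULE_ZONE_NAMES:
        raise ValueError(f"unknown nodule zone {zone!r}")
    spec = holo.spec
    if proton_access is None:
        proton_access = spec.bacteroid_proton_access
    btag = f"Bacteroid{zone}"
    ptag = f"Nodule{zone}"
    if btag in holo.tissue_index:
        raise ValueError(f"zone {zone} already carries a bacteroid")
    pbs = f"PBS_{zone}"

    rep = replicate_tissue(bacterium, btag)
    # boundary compartment -> peribacteroid space
    rep.remove_reactions([r for r in rep.reactions if r.id.startswith(f"{btag}_EX_")])
    for met in rep.metabolites:
        if met.compartment == f"{btag}_e":
            base = met.id[len(btag) + 1 : -2]
            met.id = f"{pbs}_{base}"
            met.compartment = pbs
    rep.repair()
    model = holo.model
    _merge(model, rep)
    holo.tissue_index[btag] = {
        "reactions": {r.id for r in rep.reactions},
        "genes": {g.id for g in rep.genes},
    }

    def transfer(base: str, reversible: bool, cost: bool, cap: float = 1000.0) -> str:
        rid = f"T_{ptag}__{pbs}__{base}"
        rxn = Reaction(
            rid,
            name=f"{base} transfer {ptag}->{pbs}",
            lower_bound=-cap if reversible else 0.0,
            upper_bound=cap,
        )
        rxn.subsystem = "peribacteroid transfer"
        model.add_reactions([rxn])
        src = model.metabolites.get_by_id(f"{ptag}_{base}_c")
        if not model.metabolites.has_id(f"{pbs}_{base}"):
            # species the bacteroid copy cannot use; dead end, pruned later
            formula, charge, name = SPECIES[base]
            orphan = Metabolite(
                f"{pbs}_{base}", formula=formula, name=name, compartment=pbs
            )
            orphan.charge = charge
            model.add_metabolites([orphan])
        dst = model.metabolites.get_by_id(f"{pbs}_{base}")
        rxn.add_metabolites({src: -1.0, dst: 1.0})
        if cost and spec.transport_atp_cost:
            rxn.add_metabolites(
                {
                    model.metabolites.get_by_id(mid): coef
                    for mid, coef in _hydrolysis_terms(
                        ptag, spec.transport_atp_cost
                    ).items()
                }
            )
        holo.link_reactions.append(rid)
        return rid

    if zone == "III":
        carbon = list(spec.zone3_carbon_whitelist)
        if spec.sucrose_bacteroid_variant:
            carbon.append("sucr")
        cap = spec.zone3_carbon_cap
    else:
        carbon = [*C4_DICARBOXYLATES, "sucr", "triose"]
        cap = 1000.0
    for base in carbon:
        transfer(base, reversible=False, cost=True, cap=cap)
    for base in ("o2", "co2", "h2o", "n2", "h2", "nh3", "ala"):
        transfer(base, reversible=True, cost=False)

    # surplus PBS protons drain back into the plant cytosol (never the reverse)
    relief = Reaction(
        f"T_{pbs}__{ptag}__h_release",
        name=f"PBS proton release to {ptag}",
        lower_bound=0.0,
        upper_bound=1000.0,
    )
    relief.subsystem = "peribacteroid transfer"
    model.add_reactions([relief])
    relief.add_metabolites(
        {
            model.metabolites.get_by_id(f"{pbs}_h"): -1.0,
            model.metabolites.get_by_id(f"{ptag}_h_c"): 1.0,
        }
    )
    holo.link_reactions.append(relief.id)

    if proton_access:
        n = spec.proton_per_pump_atp
        pump = Reaction(
            f"PUMP_H_{zone}",
            name=f"plant PBS proton pump (zone {zone})",
            lower_bound=0.0,
            upper_bound=1000.0,
        )
        pump.subsystem = "peribacteroid transfer"
        model.add_reactions([pump])
        # atp + h2o + (n-1) h_plant -> adp + pi + n h_PBS  (balanced for any n)
        stoich = _hydrolysis_terms(ptag, 1.0)
        stoich[f"{ptag}_h_c"] = stoich.get(f"{ptag}_h_c", 0.0) - n
        pump.add_metabolites(
            {model.metabolites.get_by_id(m): c for m, c in stoich.items() if c}
        )
        pump.add_metabolites({model.metabolites.get_by_id(f"{pbs}_h"): n})
        holo.link_reactions.append(pump.id)
    return holo


# ---------------------------------------------------------------------------
# objective


def _trunc5(x: float) -> float:
    return math.floor(x * 1e5) / 1e5


def build_objective(spec: HolobiontSpec, f: float | None = None) -> dict[str, float]:
    """Composite biomass weights for nodulation fraction *f*.

    At the default f = 0.02 the weights are the reference constants (shoot
    0.65333, root 0.32666, zone weights as configured; total 0.99999 -- the
    printed five-decimal values).  For other f, shoot/root carry (1 - f) at
    the configured shoot:root ratio (truncated to 5 decimals, which is what
    reproduces the reference constants) and zone weights scale by f / 0.02.
    """
    if f is None:
        f = spec.nodulation_fraction
    if not 0 <= f < 1:
        raise ValueError("nodulation fraction must be in [0, 1)")
    r = spec.shoot_root_ratio
    weights = {
        "Shoot": _trunc5((1 - f) * r / (1 + r)),
        "Root": _trunc5((1 - f) * 1 / (1 + r)),
    }
    if f > 0:
        for key, w in spec.zone_biomass_weights.items():
            weights[key] = w * f / 0.02
    return weights


def _attach_objective(holo: HolobiontModel, weights: dict[str, float]) -> None:
    """(Re)build the overall-biomass drain reaction from weight map."""
    model = holo.model
    if model.reactions.has_id(OBJECTIVE_ID):
        model.remove_reactions([model.reactions.get_by_id(OBJECTIVE_ID)])
    drain = Reaction(OBJECTIVE_ID, name="overall biomass drain",
                     lower_bound=0.0, upper_bound=1000.0)
    drain.subsystem = "objective"
    model.add_reactions([drain])
    stoich = {}
    for key, w in weights.items():
        tissue = _WEIGHT_TISSUE[key]
        stoich[model.metabolites.get_by_id(f"{tissue}_biomass_c")] = -w
    drain.add_metabolites(stoich)
    model.objective = OBJECTIVE_ID
    holo.objective_terms = dict(weights)


def plant_growth(holo: HolobiontModel, objective_value: float) -> float:
    """Convert overall-biomass flux to shoot+root growth (g h^-1 gDW^-1)."""
    w = holo.objective_terms
    return objective_value * (w.get("Shoot", 0.0) + w.get("Root", 0.0))


# ---------------------------------------------------------------------------
# constraints


def _set_exchange(
    model: Model, rid: str, lb: float, ub: float, required: bool = True
) -> None:
    if not model.reactions.has_id(rid):
        # a pruned exchange is permanently closed; only closing it is legal
        if required or lb != 0.0 or ub != 0.0:
            raise KeyError(f"exchange reaction {rid} absent")
        return
    model.reactions.get_by_id(rid).bounds = (lb, ub)


def apply_constraints(holo: HolobiontModel, nitrogen: str = "n2") -> HolobiontModel:
    """Apply the physiological constraint set.

    Per-tissue environment exchanges: light and CO2 enter at the shoot (caps
    ``light_cap``/``co2_cap``); mineral nitrogen enters at the root and is
    closed when ``nitrogen == "n2"``; every tissue breathes O2/CO2/water/
    protons; nodule zones additionally exchange N2 (in) and H2 (out); the
    zone III O2 uptake is capped at ``zone3_o2_cap``.  All other replicated
    exchanges are closed.  Maintenance ATP hydrolysis is forced at the
    spec rates via lower bounds.
    """
    model = holo.model
    spec = holo.spec
    # close every replicated exchange (and the standalone per-tissue biomass
    # demands -- biomass leaves only through the weighted overall drain),
    # then open the whitelist
    for rxn in model.reactions:
        if "_EX_" in rxn.id or rxn.id.endswith("_DM_biomass"):
            rxn.bounds = (0.0, 0.0)
    _set_exchange(model, "Shoot_EX_photon", -spec.light_cap, 0.0)
    _set_exchange(model, "Shoot_EX_co2", -spec.co2_cap, 1000.0)
    for tissue in PLANT_ZONES:
        _set_exchange(model, f"{tissue}_EX_o2", -1000.0, 1000.0)
        _set_exchange(model, f"{tissue}_EX_h2o", -1000.0, 1000.0)
        _set_exchange(model, f"{tissue}_EX_h", -1000.0, 1000.0)
        if tissue != "Shoot":
            _set_exchange(model, f"{tissue}_EX_co2", -1000.0, 1000.0)
    for zone in ["NoduleI", *NODULE_PLANT_ZONES]:
        _set_exchange(model, f"{zone}_EX_n2", -1000.0, 0.0)
        _set_exchange(model, f"{zone}_EX_h2", 0.0, 1000.0)
    _set_exchange(model, "NoduleIII_EX_o2", -spec.zone3_o2_cap, 1000.0)
    set_nitrogen_source(holo, nitrogen)
    for tissue, rate in spec.maintenance.items():
        rid = f"{tissue}_ATPM" if model.reactions.has_id(f"{tissue}_ATPM") else f"{tissue}_NGAM"
        model.reactions.get_by_id(rid).lower_bound = rate
    return holo


def set_nitrogen_source(
    holo: HolobiontModel, nitrogen: str, nh4_cap: float = 1000.0
) -> None:
    """``"n2"``: root nitrate/ammonium uptake closed (export of surplus
    ammonium stays open); ``"ammonium"``: root ammonium uptake up to
    *nh4_cap*."""
    model = holo.model
    if nitrogen == "n2":
        _set_exchange(model, "Root_EX_nh4", 0.0, 1000.0)
        _set_exchange(model, "Root_EX_no3", 0.0, 0.0, required=False)
    elif nitrogen == "ammonium":
        _set_exchange(model, "Root_EX_nh4", -nh4_cap, 1000.0)
        _set_exchange(model, "Root_EX_no3", 0.0, 0.0, required=False)
    else:
        raise ValueError(f"unknown nitrogen source {nitrogen!r}")


# ---------------------------------------------------------------------------
# build orchestration


def build_holobiont(
    plant: Model,
    bacterium: Model,
    spec: HolobiontSpec | None = None,
    calls: ExpressionCallSet | None = None,
    transport_table: list[TransportRow] | None = None,
    nitrogen: str = "n2",
    prune: bool = True,
) -> HolobiontModel:
    """Full integration pipeline; returns a feasible gated, pruned holobiont."""
    spec = spec or HolobiontSpec()
    model = Model("holobiont")
    model.solver = "glpk"
    holo = HolobiontModel(
        model=model, tissue_index={}, link_reactions=[], objective_terms={}, spec=spec
    )
    for tag in PLANT_ZONES:
        rep = replicate_tissue(plant, tag)
        _merge(model, rep)
        holo.tissue_index[tag] = {
            "reactions": {r.id for r in rep.reactions},
            "genes": {g.id for g in rep.genes},
        }
    for zone in NODULE_ZONE_NAMES:
        embed_bacteroid(holo, bacterium, zone)
    link_tissues(holo, transport_table or default_transport_table(spec))
    if calls is not None:
        for zone in calls.zones():
            gate_zone(holo, zone, calls)
    _attach_objective(holo, build_objective(spec))
    apply_constraints(holo, nitrogen=nitrogen)
    if prune:
        pruned, removed = remove_dead_ends(model)
        pruned.solver = "glpk"
        holo.model = pruned
        kept = {r.id for r in pruned.reactions}
        gone = set(removed)
        for entry in holo.tissue_index.values():
            entry["reactions"] &= kept
            entry["genes"] &= {g.id for g in pruned.genes}
        holo.link_reactions = [r for r in holo.link_reactions if r not in gone]
    return holo


def rescale_nodulation(holo: HolobiontModel, f: float) -> HolobiontModel:
    """Return a copy rebalanced to nodulation fraction *f*.

    The objective drain keeps only shoot/root terms (rescaled to sum to one)
    while the nodule and bacteroid biomass components are co-consumed by the
    same drain at f/(1-f) times their default internal proportions -- a sink
    ratio-locked to plant growth.  Nodule/bacteroid maintenance bounds and the
    zone III O2 cap scale linearly in f/0.02.  The objective value of the
    result is shoot+root growth directly.
    """
    out = holo.copy()
    set_nodulation_inplace(out, f)
    return out


def set_nodulation_inplace(holo: HolobiontModel, f: float) -> None:
    """In-place variant of :func:`rescale_nodulation` (cheap, scan-friendly)."""
    if not 0 <= f < 1:
        raise ValueError("nodulation fraction must be in [0, 1)")
    spec = holo.spec
    model = holo.model
    r = spec.shoot_root_ratio
    weights = {"Shoot": r / (1 + r), "Root": 1 / (1 + r)}
    if f > 0:
        zone_total = 0.02  # default zone weights sum
        for key, w in spec.zone_biomass_weights.items():
            if model.metabolites.has_id(f"{_WEIGHT_TISSUE[key]}_biomass_c"):
                weights[key] = (w / zone_total) * f / (1 - f)
    _attach_objective(holo, weights)
    # record shoot/root share for plant_growth bookkeeping: here objective IS
    # plant growth, so overwrite terms to make plant_growth() the identity
    holo.objective_terms = {"Shoot": weights["Shoot"], "Root": weights["Root"]}
    scale = f / 0.02
    for tissue, rate in spec.maintenance.items():
        if tissue in ("Shoot", "Root"):
            continue
        rid = (
            f"{tissue}_ATPM"
            if model.reactions.has_id(f"{tissue}_ATPM")
            else f"{tissue}_NGAM"
        )
        if model.reactions.has_id(rid):
            model.reactions.get_by_id(rid).lower_bound = rate * scale
    if model.reactions.has_id("NoduleIII_EX_o2"):
        model.reactions.get_by_id("NoduleIII_EX_o2").lower_bound = (
            -spec.zone3_o2_cap * scale
        )


def nitrogenase_reaction_id(holo: HolobiontModel) -> str:
    rid = "BacteroidIII_NITROGENASE"
    if not holo.model.reactions.has_id(rid):
        raise KeyError("zone III nitrogenase reaction absent from holobiont")
    return rid


def fix_fixation_efficiency(
    holo: HolobiontModel, efficiency: float, f: float | None = None
) -> None:
    """Pin zone III nitrogenase flux to efficiency * f (umol N2 h^-1 gDW^-1).

    "Efficiency" is nitrogenase flux per gram nodule dry weight; the per-plant
    flux is e*f.  Pass efficiency=None via :func:`free_fixation` to relax.
    """
    if f is None:
        f = holo.spec.nodulation_fraction
    rxn = holo.model.reactions.get_by_id(nitrogenase_reaction_id(holo))
    rxn.bounds = (efficiency * f, efficiency * f)


def free_fixation(holo: HolobiontModel) -> None:
    rxn = holo.model.reactions.get_by_id(nitrogenase_reaction_id(holo))
    rxn.bounds = (0.0, 1000.0)
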