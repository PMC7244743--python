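"""Model I/O, validation, mass/charge balancing and structural pruning.

The in-memory model container is :class:`cobra.Model`; every function here
accepts and returns cobra objects.  Two on-disk dialects are supported:

* ``sbml`` -- SBML L2/L3 with FBC bounds and gene associations, through
  :mod:`cobra.io` (written as L3/FBC).
* ``tabular`` -- a reviewable plain-text dialect: a directory holding
  ``metabolites.tsv`` (id, name, formula, charge, compartment) and
  ``reactions.tsv`` (id, name, equation, lower_bound, upper_bound, gene_rule,
  subsystem, objective_coefficient).  Equations use cobra's arrow syntax,
  e.g. ``a_c + 2 b_c --> c_c``.

Flux units are umol h^-1 (g plant dry weight)^-1 throughout, except biomass
drains which are g biomass h^-1 (g plant DW)^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from cobra import Metabolite, Model, Reaction
from cobra.core.gene import GPR

#: net-imbalance tolerance for mass/charge balance checks
BALANCE_TOL = 1e-6
#: fluxes below this magnitude are treated as zero
FLUX_ZERO_TOL = 1e-9

_REACTION_COLUMNS = [
    "id",
    "name",
    "equation",
    "lower_bound",
    "upper_bound",
    "gene_rule",
    "subsystem",
    "objective_coefficient",
]
_METABOLITE_COLUMNS = ["id", "name", "formula", "charge", "compartment"]


class ModelValidationError(ValueError):
    """A model violates a structural invariant (dangling ids, bad bounds...)."""


class ObjectivePrunedError(RuntimeError):
    """Dead-end pruning would remove a reaction carrying objective weight."""


# ---------------------------------------------------------------------------
# reading / writing


def _infer_dialect(path: Path) -> str:
    if path.suffix.lower() in {".xml", ".sbml"}:
        return "sbml"
    return "tabular"


def read_model(path: str | Path, dialect: str | None = None) -> Model:
    """Read a model from *path* in the named dialect.

    ``dialect`` is ``"sbml"`` or ``"tabular"``; if omitted it is inferred from
    the path (``.xml``/``.sbml`` -> sbml, directory -> tabular).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "sbml":
        from cobra.io import read_sbml_model

        model = read_sbml_model(str(path))
    elif dialect == "tabular":
        model = _read_tabular(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    validate_model(model)
    return model


def write_model(model: Model, path: str | Path, dialect: str | None = None) -> Path:
    """Write *model* to *path*; the inverse of :func:`read_model`."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "sbml":
        from cobra.io import write_sbml_model

        write_sbml_model(model, str(path))
    elif dialect == "tabular":
        _write_tabular(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _read_tabular(path: Path) -> Model:
    met_file = path / "metabolites.tsv"
    rxn_file = path / "reactions.tsv"
    for f in (met_file, rxn_file):
        if not f.exists():
            raise FileNotFoundError(f)
    mets = pd.read_csv(met_file, sep="\t", dtype=str).fillna("")
    rxns = pd.read_csv(rxn_file, sep="\t", dtype=str).fillna("")
    model = Model(path.name)
    metabolites = []
    for row in mets.itertuples(index=False):
        if not row.compartment:
            raise ModelValidationError(f"metabolite {row.id}: empty compartment")
        met = Metabolite(
            row.id,
            name=row.name,
            formula=row.formula,  # "" = massless species (photons, lumps)
            compartment=row.compartment,
        )
        met.charge = int(row.charge) if row.charge != "" else None
        metabolites.append(met)
    model.add_metabolites(metabolites)
    objective = {}
    for row in rxns.itertuples(index=False):
        rxn = Reaction(
            row.id,
            name=row.name,
            lower_bound=float(row.lower_bound),
            upper_bound=float(row.upper_bound),
        )
        rxn.subsystem = row.subsystem
        model.add_reactions([rxn])
        try:
            rxn.build_reaction_from_string(row.equation, verbose=False)
        except Exception as exc:  # noqa: BLE001 - re-raise with location
            raise ModelValidationError(
                f"reaction {row.id}: cannot parse equation {row.equation!r}: {exc}"
            ) from exc
        # re-apply: build_reaction_from_string resets bounds from the arrow
        rxn.bounds = (float(row.lower_bound), float(row.upper_bound))
        if row.gene_rule:
            rxn.gene_reaction_rule = row.gene_rule
        coef = float(row.objective_coefficient or 0.0)
        if coef:
            objective[rxn] = coef
    if objective:
        model.objective = objective
    return model


def _write_tabular(model: Model, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    mets = pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name or "",
                "formula": m.formula or "",
                "charge": "" if m.charge is None else int(m.charge),
                "compartment": m.compartment,
            }
            for m in sorted(model.metabolites, key=lambda m: m.id)
        ],
        columns=_METABOLITE_COLUMNS,
    )
    objective = {r.id: c for r, c in _objective_reactions(model).items()}
    rxns = pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name or "",
                "equation": r.build_reaction_string(),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_reaction_rule,
                "subsystem": r.subsystem or "",
                "objective_coefficient": objective.get(r.id, 0.0),
            }
            for r in sorted(model.reactions, key=lambda r: r.id)
        ],
        columns=_REACTION_COLUMNS,
    )
    mets.to_csv(path / "metabolites.tsv", sep="\t", index=False)
    rxns.to_csv(path / "reactions.tsv", sep="\t", index=False)


def _objective_reactions(model: Model) -> dict[Reaction, float]:
    coefs = {}
    for rxn in model.reactions:
        c = rxn.objective_coefficient
        if c:
            coefs[rxn] = c
    return coefs


def validate_model(model: Model) -> None:
    """Raise :class:`ModelValidationError` on broken structural invariants."""
    problems = []
    seen = set()
    for met in model.metabolites:
        if met.id in seen:
            problems.append(f"duplicate metabolite id {met.id}")
        seen.add(met.id)
        if not met.compartment:
            problems.append(f"metabolite {met.id}: empty compartment")
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            problems.append(f"reaction {rxn.id}: lower bound above upper bound")
        if not rxn.metabolites:
            problems.append(f"reaction {rxn.id}: empty stoichiometry")
        if rxn.id.startswith("EX_") and len(rxn.metabolites) != 1:
            problems.append(f"exchange reaction {rxn.id}: must have one metabolite")
        rule_genes = rxn.gpr.genes if rxn.gene_reaction_rule else set()
        for g in rule_genes:
            if g not in model.genes:
                problems.append(f"reaction {rxn.id}: unknown gene {g} in rule")
    if problems:
        raise ModelValidationError("; ".join(problems))


# ---------------------------------------------------------------------------
# mass / charge balance


@dataclass
class BalanceReport:
    """Element-wise and charge imbalance of a single reaction.

    ``balanced`` is true iff every net element count and the net charge are
    zero within :data:`BALANCE_TOL`.  ``undetermined`` is set (and ``balanced``
    false) when some participating metabolite lacks a parseable formula or a
    charge, in which case no verdict is possible.
    """

    reaction_id: str
    element_imbalance: dict[str, float] = field(default_factory=dict)
    charge_imbalance: float = 0.0
    balanced: bool = True
    undetermined: bool = False


def check_balance(reaction: Reaction, model: Model | None = None) -> BalanceReport:
    """Net element/charge balance of *reaction* (negative coeff = consumed).

    Massless species (photons) may carry an empty formula string, which counts
    as zero atoms; a missing (``None``) formula or charge makes the report
    undetermined rather than raising.
    """
    elements: dict[str, float] = {}
    charge = 0.0
    for met, coef in reaction.metabolites.items():
        if met.charge is None or met.formula is None:
            return BalanceReport(reaction.id, undetermined=True, balanced=False)
        try:
            met_elements = met.elements
        except Exception:  # noqa: BLE001 - unparseable formula
            return BalanceReport(reaction.id, undetermined=True, balanced=False)
        for element, count in met_elements.items():
            elements[element] = elements.get(element, 0.0) + coef * count
        charge += coef * met.charge
    imbalance = {e: v for e, v in elements.items() if abs(v) > BALANCE_TOL}
    balanced = not imbalance and abs(charge) <= BALANCE_TOL
    return BalanceReport(
        reaction.id,
        element_imbalance=imbalance,
        charge_imbalance=charge if abs(charge) > BALANCE_TOL else 0.0,
        balanced=balanced,
    )


def is_boundary_like(reaction: Reaction) -> bool:
    """Exchanges, sinks and biomass drains; skipped by whole-model balancing.

    Biomass assembly reactions convert mmol-scale precursors into a gram of
    lumped biomass and are stoichiometric by convention, not by chemistry.
    """
    if len(reaction.metabolites) == 1:
        return True
    if any(key in reaction.id.upper() for key in ("BIOMASS", "SINK_", "DM_")):
        return True
    return any("biomass" in met.id.lower() for met in reaction.metabolites)


# ---------------------------------------------------------------------------
# dead-end pruning


def remove_dead_ends(
    model: Model, drop_closed: bool = True
) -> tuple[Model, list[str]]:
    """Iteratively remove reactions producing/consuming dead-end metabolites.

    A metabolite is a dead end when, over the open reactions of the model, it
    is only ever produced or only ever consumed; reversible reactions count on
    both sides, and single-metabolite boundary reactions count as ordinary
    producers/consumers (an exchange therefore rescues an otherwise dead
    metabolite).  Reactions closed to zero flux (both bounds 0) are dropped
    first when ``drop_closed`` -- this is how expression-gated reaction space
    is physically removed.  Iterates to the unique fixpoint; the input model
    is left untouched.

    Raises :class:`ObjectivePrunedError` if pruning would delete a reaction
    with nonzero objective weight.
    """
    pruned = model.copy()
    objective_ids = {r.id for r in _objective_reactions(pruned)}
    removed: list[str] = []

    def _drop(rxns):
        hit = [r for r in rxns if r.id in objective_ids]
        if hit:
            raise ObjectivePrunedError(
                f"pruning would remove objective reaction(s) {[r.id for r in hit]}"
            )
        removed.extend(r.id for r in rxns)
        pruned.remove_reactions(rxns, remove_orphans=False)

    if drop_closed:
        closed = [
            r for r in pruned.reactions if r.lower_bound == 0 and r.upper_bound == 0
        ]
        if closed:
            _drop(closed)

    while True:
        producers: dict[str, int] = {}
        consumers: dict[str, int] = {}
        for rxn in pruned.reactions:
            fwd = rxn.upper_bound > 0
            rev = rxn.lower_bound < 0
            for met, coef in rxn.metabolites.items():
                makes = (coef > 0 and fwd) or (coef < 0 and rev)
                takes = (coef < 0 and fwd) or (coef > 0 and rev)
                if makes:
                    producers[met.id] = producers.get(met.id, 0) + 1
                if takes:
                    consumers[met.id] = consumers.get(met.id, 0) + 1
        dead = {
            m.id
            for m in pruned.metabolites
            if m.reactions
            and (producers.get(m.id, 0) == 0 or consumers.get(m.id, 0) == 0)
        }
        if not dead:
            break
        doomed = [
            rxn
            for rxn in pruned.reactions
            if any(met.id in dead for met in rxn.metabolites)
        ]
        if not doomed:
            break
        _drop(doomed)

    orphans = [m for m in pruned.metabolites if not m.reactions]
    if orphans:
        pruned.remove_metabolites(orphans)
    _prune_unused_genes(pruned)
    return pruned, removed


def _prune_unused_genes(model: Model) -> None:
    unused = [g for g in model.genes if not g.reactions]
    if unused:
        # cobra's gene list is derived from GPRs; drop stale entries directly
        for gene in unused:
            model.genes.remove(gene)
            gene._model = None


# ---------------------------------------------------------------------------
# gene rules


def evaluate_gene_rule(
    rule: str | GPR, inactive_genes: set[str], known_genes: set[str] | None = None
) -> bool:
    """Evaluate a boolean AND/OR gene rule with *inactive_genes* knocked out.

    An empty rule means the reaction is not gene-gated and always evaluates
    true.  Inactive genes absent from the rule (and, if given, from
    *known_genes*) are ignored with a warning: deleting a gene that a rule
    never mentions can never disable the reaction.
    """
    gpr = GPR.from_string(rule) if isinstance(rule, str) else rule
    if gpr.body is None:
        return True
    rule_genes = gpr.genes
    universe = rule_genes | (known_genes or set())
    unknown = set(inactive_genes) - universe
    if unknown:
        warnings.warn(
            f"inactive genes not present in rule/model ignored: {sorted(unknown)}",
            stacklevel=2,
        )
    return gpr.eval(knockouts=set(inactive_genes) & rule_genes)
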