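"""Constrain a zone's reaction space from gene on/off expression calls.

A reaction is closed (both flux bounds zero) in a zone copy exactly when its
gene rule is non-empty and evaluates false with the zone's off-genes marked
inactive.  Reactions without a gene rule (exchanges, diffusion transport,
spontaneous chemistry) are never gated: gating acts on gene evidence only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from nodulefba.core import evaluate_gene_rule

if TYPE_CHECKING:  # pragma: no cover
    from nodulefba.assembly import HolobiontModel
    from nodulefba.toy import ExpressionCallSet


@dataclass
class GatingReport:
    zone: str
    closed_reaction_ids: list[str] = field(default_factory=list)
    kept_ungated: list[str] = field(default_factory=list)
    calls_used: dict[str, bool] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "zone": self.zone,
            "closed_reaction_ids": sorted(self.closed_reaction_ids),
            "kept_ungated": sorted(self.kept_ungated),
            "calls_used": dict(sorted(self.calls_used.items())),
        }


def gate_zone(
    holo: "HolobiontModel", zone: str, calls: "ExpressionCallSet"
) -> tuple["HolobiontModel", GatingReport]:
    """Close the reactions of *zone* whose gene rules fail the zone's calls.

    Calls are keyed by base (unprefixed) gene ids; the zone's gene copies are
    ``<zone>_<base>``.  Gating only touches the zone's own reaction copies and
    is idempotent and monotone (adding off-genes can only close more).
    """
    if zone not in holo.tissue_index:
        raise KeyError(f"unknown tissue/zone {zone!r}")
    off_base = calls.off_genes(zone)  # raises if the zone has no calls
    inactive = {f"{zone}_{g}" for g in off_base}
    zone_genes = holo.tissue_index[zone]["genes"]
    report = GatingReport(zone=zone, calls_used={g: False for g in off_base})
    model = holo.model
    for rid in sorted(holo.tissue_index[zone]["reactions"]):
        if not model.reactions.has_id(rid):
            continue
        rxn = model.reactions.get_by_id(rid)
        if not rxn.gene_reaction_rule:
            report.kept_ungated.append(rid)
            continue
        alive = evaluate_gene_rule(
            rxn.gpr, inactive & zone_genes, known_genes=zone_genes
        )
        if not alive:
            rxn.bounds = (0.0, 0.0)
            report.closed_reaction_ids.append(rid)
    return holo, report


def call_from_abundance(table: pd.DataFrame, threshold_quantile: float):
    """Binary on/off calls from a gene x zone abundance matrix.

    A gene is called on in a zone iff its abundance is at least the given
    quantile of that zone's *nonzero* abundances.  Zones whose column is all
    zero call every gene off.  Deterministic; abundances must be >= 0.
    """
    from nodulefba.toy import ExpressionCallSet

    if table.size == 0:
        raise ValueError("empty abundance matrix")
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    calls: dict[str, dict[str, bool]] = {}
    for j, zone in enumerate(table.columns):
        col = values[:, j]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            threshold = np.inf
        else:
            threshold = np.quantile(nonzero, threshold_quantile)
        calls[str(zone)] = {
            str(gene): bool(col[i] >= threshold)
            for i, gene in enumerate(table.index)
        }
    return ExpressionCallSet(calls)
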