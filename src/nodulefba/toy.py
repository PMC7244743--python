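"""Deterministic miniature plant and rhizobium models plus zone expression calls.

The generated pair is a desk-scale stand-in for a genome-scale plant
reconstruction and a rhizobium reconstruction, carrying exactly the metabolic
structure the nodule analysis assumes:

* plant -- light/CO2 fixation to a triose pool, sucrose synthesis and
  hydrolysis, glycolysis to PEP (substrate-level ATP + NADH), a PEP-carboxylase
  route to oxaloacetate and the C4-dicarboxylates (malate, fumarate,
  succinate), a mitochondrial terminal oxidase (NADH oxidation coupled to ATP
  synthesis), nitrate reduction and GS/GOGAT ammonium assimilation into an
  L-alanine amino-acid lump, biomass, and an ATP-hydrolysis maintenance
  reaction;
* bacterium -- H+-symport uptake of succinate/malate/fumarate (one external
  proton co-transported per dicarboxylate), optional sucrose uptake and
  hydrolysis, glucose and triose uptake, a lumped TCA cycle, a terminal
  oxidase coupled to ATP synthase, nitrogenase
  (N2 + 8 H+ + 8 e- + n ATP -> 2 NH3 + H2, electrons carried as 4 NADH),
  ammonia and L-alanine export, GS/GOGAT, biomass via two gene-gated anabolic
  precursors, and an NGAM ATP-hydrolysis reaction.

Every internal reaction is element- and charge-balanced: reactions are sums of
individually balanced blocks (real elemental formulas, ATP synthesis/hydrolysis
as the standard condensation ADP + Pi + H+ <-> ATP + H2O).  Photons are
massless species with an empty formula.

Units: umol h^-1 gDW^-1 for fluxes; biomass drains make 1 g of biomass from
mmol-scale precursor amounts written in umol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from cobra import Metabolite, Model, Reaction

UB = 1000.0
MAINT_UB = 1e6

#: base species: id -> (formula, charge, name)
SPECIES: dict[str, tuple[str, int, str]] = {
    "photon": ("", 0, "photon"),
    "co2": ("CO2", 0, "carbon dioxide"),
    "o2": ("O2", 0, "oxygen"),
    "h2o": ("H2O", 0, "water"),
    "h": ("H", 1, "proton"),
    "h2": ("H2", 0, "dihydrogen"),
    "n2": ("N2", 0, "dinitrogen"),
    "nh3": ("H3N", 0, "ammonia"),
    "nh4": ("H4N", 1, "ammonium"),
    "no3": ("NO3", -1, "nitrate"),
    "pi": ("HO4P", -2, "phosphate"),
    "atp": ("C10H12N5O13P3", -4, "ATP"),
    "adp": ("C10H12N5O10P2", -3, "ADP"),
    "nad": ("C21H26N7O14P2", -1, "NAD+"),
    "nadh": ("C21H27N7O14P2", -2, "NADH"),
    "triose": ("C3H6O3", 0, "triose pool (glyceraldehyde)"),
    "sucr": ("C12H22O11", 0, "sucrose"),
    "glc": ("C6H12O6", 0, "D-glucose"),
    "xyl": ("C5H10O5", 0, "D-xylose"),
    "pep": ("C3H2O6P", -3, "phosphoenolpyruvate"),
    "pyr": ("C3H3O3", -1, "pyruvate"),
    "oaa": ("C4H2O5", -2, "oxaloacetate"),
    "mal": ("C4H4O5", -2, "L-malate"),
    "fum": ("C4H2O4", -2, "fumarate"),
    "succ": ("C4H4O4", -2, "succinate"),
    "akg": ("C5H4O5", -2, "2-oxoglutarate"),
    "glu": ("C5H8NO4", -1, "L-glutamate"),
    "gln": ("C5H10N2O3", 0, "L-glutamine"),
    "ala": ("C3H7NO2", 0, "L-alanine (amino-acid lump)"),
    "prec1": ("C9H9O9", -3, "carbon-skeleton precursor"),
    "prec2": ("C6H14N2O4", 0, "amino precursor"),
    "biomass": ("", 0, "biomass"),
}

C4_DICARBOXYLATES = ("succ", "mal", "fum")

# --- balanced building blocks (dicts base-species-in-cytosol -> coefficient)

ATP_SYNTH = {"adp": -1, "pi": -1, "h": -1, "atp": 1, "h2o": 1}
ATP_HYD = {k: -v for k, v in ATP_SYNTH.items()}
NADH_OX = {"nadh": -1, "h": -1, "o2": -0.5, "nad": 1, "h2o": 1}


def _combine(*terms: tuple[float, dict[str, float]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for weight, block in terms:
        for met, coef in block.items():
            out[met] = out.get(met, 0.0) + weight * coef
    return {m: c for m, c in out.items() if abs(c) > 1e-12}


@dataclass(frozen=True)
class ToyConfig:
    """Generation parameters; defaults define the reference fixture.

    seed drives only the random dead-end decoy reactions; the metabolic core
    is fully deterministic.  ``nitrogenase_atp_per_n2`` defaults to the
    textbook 16 ATP per N2; ``o2_per_atp_respiration`` is mol O2 consumed per
    mol ATP made by oxidative phosphorylation (0.2 = P/O ratio 2.5);
    ``biomass_scale`` multiplies precursor demands of both biomass reactions.
    """

    seed: int = 1
    include_sucrose_bacteroid_path: bool = False
    nitrogenase_atp_per_n2: float = 16.0
    o2_per_atp_respiration: float = 0.2
    decoy_reaction_count: int = 6
    biomass_scale: float = 1.0

    def __post_init__(self):
        if self.nitrogenase_atp_per_n2 <= 0:
            raise ValueError("nitrogenase_atp_per_n2 must be positive")
        if self.o2_per_atp_respiration <= 0:
            raise ValueError("o2_per_atp_respiration must be positive")
        if self.decoy_reaction_count < 0:
            raise ValueError("decoy_reaction_count must be non-negative")

    @property
    def atp_per_nadh(self) -> float:
        return 0.5 / self.o2_per_atp_respiration


class _Builder:
    """Accumulates metabolites/reactions for one single-compartment organism."""

    def __init__(self, model_id: str):
        self.model = Model(model_id)
        self._mets: dict[str, Metabolite] = {}

    def met(self, key: str) -> Metabolite:
        if key not in self._mets:
            base, comp = key.rsplit("_", 1)
            formula, charge, name = SPECIES[base]
            m = Metabolite(
                key, formula=formula, name=name, compartment=comp
            )
            m.charge = charge
            self._mets[key] = m
            self.model.add_metabolites([m])
        return self._mets[key]

    def rxn(
        self,
        rid: str,
        stoich: dict[str, float],
        gene: str = "",
        bounds: tuple[float, float] = (0.0, UB),
        name: str = "",
        subsystem: str = "",
    ) -> Reaction:
        r = Reaction(rid, name=name or rid, lower_bound=bounds[0], upper_bound=bounds[1])
        r.subsystem = subsystem
        self.model.add_reactions([r])
        r.add_metabolites({self.met(k): v for k, v in stoich.items()})
        if gene:
            r.gene_reaction_rule = gene
        return r

    def cyt(self, block: dict[str, float], comp: str = "c") -> dict[str, float]:
        return {f"{k}_{comp}": v for k, v in block.items()}

    def exchange(self, base: str, lb: float, ub: float = UB) -> Reaction:
        return self.rxn(f"EX_{base}", {f"{base}_e": -1}, bounds=(lb, ub), name=f"{base} exchange")

    def diffusion(self, base: str, reversible: bool = True, gene: str = "") -> Reaction:
        bounds = (-UB, UB) if reversible else (0.0, UB)
        return self.rxn(
            f"T_{base}", {f"{base}_e": -1, f"{base}_c": 1}, gene=gene, bounds=bounds,
            name=f"{base} transport", subsystem="transport",
        )


def _add_decoys(b: _Builder, rng: np.random.Generator, n: int, gene_prefix: str) -> None:
    """Gene-gated reactions feeding structurally dead-end metabolites."""
    substrates = ["triose_c", "pyr_c", "mal_c", "h2o_c"]
    for i in range(n):
        sub = substrates[int(rng.integers(len(substrates)))]
        base = sub.rsplit("_", 1)[0]
        formula, charge, _ = SPECIES[base]
        dm = Metabolite(f"decoy{i}_c", formula=formula, name=f"decoy {i}", compartment="c")
        dm.charge = charge
        b.model.add_metabolites([dm])
        r = Reaction(f"DECOY{i}", lower_bound=0.0, upper_bound=UB)
        r.subsystem = "decoy"
        b.model.add_reactions([r])
        r.add_metabolites({b.met(sub): -1, dm: 1})
        r.gene_reaction_rule = f"{gene_prefix}_dec{i}"


def generate_toy_plant(config: ToyConfig | None = None) -> Model:
    """Miniature plant model (single cytosol ``c`` + boundary ``e``)."""
    cfg = config or ToyConfig()
    rng = np.random.default_rng(cfg.seed)
    b = _Builder("toy_plant")
    y = cfg.atp_per_nadh
    s = cfg.biomass_scale

    for base, lb, ub in [
        ("photon", -UB, 0.0),
        ("co2", -UB, UB),
        ("o2", -UB, UB),
        ("h2o", -UB, UB),
        ("h", -UB, UB),
        ("nh4", -UB, UB),
        ("no3", -UB, 0.0),
        ("sucr", 0.0, UB),
        ("n2", -UB, UB),
        ("h2", 0.0, UB),
    ]:
        b.exchange(base, lb, ub)
    b.diffusion("photon", reversible=False)
    for base in ("co2", "o2", "h2o", "h", "nh4", "n2", "h2", "sucr"):
        b.diffusion(base)
    b.diffusion("no3", reversible=False)

    c = b.cyt
    b.rxn(
        "PS",
        c({"co2": -3, "h2o": -3, "photon": -24, "triose": 1, "o2": 3}),
        gene="pg_ps", name="photosynthesis (lumped)", subsystem="photosynthesis",
    )
    b.rxn("SUCS", c({"triose": -4, "sucr": 1, "h2o": 1}), gene="pg_susy",
          name="sucrose synthase (synthesis)", subsystem="sugar metabolism")
    # two invertase isozymes: deleting either alone leaves hydrolysis intact
    b.rxn("INV", c({"sucr": -1, "h2o": -1, "triose": 4}), gene="pg_inv or pg_invB",
          name="sucrose hydrolysis", subsystem="sugar metabolism")
    gap_to_pep = {"triose": -1, "pi": -1, "nad": -1, "pep": 1, "nadh": 1, "h2o": 1, "h": 2}
    b.rxn("GLYC", c(_combine((1, gap_to_pep), (1, ATP_SYNTH))), gene="pg_gapdh",
          name="glycolysis triose->PEP", subsystem="glycolysis")
    b.rxn("PYK", c({"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1}), gene="pg_pyk",
          name="pyruvate kinase", subsystem="glycolysis")
    b.rxn("PEPC", c({"pep": -1, "co2": -1, "h2o": -1, "oaa": 1, "pi": 1, "h": 1}),
          gene="pg_pepc", name="PEP carboxylase", subsystem="C4 metabolism")
    b.rxn("MDH", c({"oaa": -1, "nadh": -1, "h": -1, "mal": 1, "nad": 1}),
          gene="pg_mdh", bounds=(-UB, UB), name="malate dehydrogenase",
          subsystem="C4 metabolism")
    b.rxn("FUMHYD", c({"mal": -1, "fum": 1, "h2o": 1}), gene="pg_fum",
          bounds=(-UB, UB), name="fumarase", subsystem="C4 metabolism")
    b.rxn("FRD", c({"fum": -1, "nadh": -1, "h": -1, "succ": 1, "nad": 1}),
          gene="pg_frd", name="fumarate reductase", subsystem="C4 metabolism")
    b.rxn("PYROX", c({"pyr": -1, "h2o": -3, "nad": -5, "co2": 3, "nadh": 5, "h": 4}),
          gene="pg_pdh", name="pyruvate oxidation (PDH + TCA lump)",
          subsystem="respiration")
    b.rxn("AKGSYN",
          c({"pyr": -1, "oaa": -1, "h2o": -1, "nad": -2, "akg": 1, "co2": 2,
             "nadh": 2, "h": 1}),
          gene="pg_cs", name="2-oxoglutarate synthesis", subsystem="respiration")
    b.rxn("MTO", c(_combine((1, NADH_OX), (y, ATP_SYNTH))), gene="pg_mto",
          name="mitochondrial terminal oxidase (oxphos lump)", subsystem="respiration")
    b.rxn("NR", c({"no3": -1, "nadh": -4, "h": -6, "nh4": 1, "h2o": 3, "nad": 4}),
          gene="pg_nr", name="nitrate reduction to ammonium", subsystem="nitrogen")
    b.rxn("AMT", c({"nh4": -1, "nh3": 1, "h": 1}), bounds=(-UB, UB),
          name="ammonium/ammonia equilibrium", subsystem="nitrogen")
    b.rxn("GS", c({"glu": -1, "nh4": -1, "atp": -1, "gln": 1, "adp": 1, "pi": 1, "h": 1}),
          gene="pg_gs", name="glutamine synthetase", subsystem="nitrogen")
    b.rxn("GOGAT", c({"gln": -1, "akg": -1, "nadh": -1, "h": -1, "glu": 2, "nad": 1}),
          gene="pg_gogat", name="glutamate synthase", subsystem="nitrogen")
    b.rxn("ALAAT", c({"pyr": -1, "glu": -1, "ala": 1, "akg": 1}), gene="pg_alaat",
          bounds=(-UB, UB), name="alanine transaminase", subsystem="nitrogen")
    b.rxn(
        "BIOMASS",
        c(_combine(
            (1, {"triose": -9000 * s, "ala": -1700 * s, "biomass": 1}),
            (30000 * s, ATP_HYD),
        )),
        gene="pg_bio", name="plant biomass", subsystem="biomass",
    )
    b.rxn("ATPM", c(ATP_HYD), bounds=(0.0, MAINT_UB),
          name="ATP maintenance", subsystem="maintenance")
    b.rxn("DM_biomass", {"biomass_c": -1}, name="biomass demand", subsystem="biomass")
    _add_decoys(b, rng, (cfg.decoy_reaction_count + 1) // 2, "pg")
    b.model.objective = "BIOMASS"
    return b.model


def generate_toy_bacterium(config: ToyConfig | None = None) -> Model:
    """Miniature rhizobium model (cytosol ``c`` + boundary ``e``)."""
    cfg = config or ToyConfig()
    rng = np.random.default_rng(cfg.seed + 7919)
    b = _Builder("toy_bacterium")
    y = cfg.atp_per_nadh
    s = cfg.biomass_scale
    c = b.cyt

    carbon_lb = {"succ": -10.0}  # default medium: 10 umol/h succinate
    for base in ["succ", "mal", "fum", "glc", "sucr", "triose", "xyl"]:
        b.exchange(base, carbon_lb.get(base, 0.0), 0.0)
    for base, lb, ub in [
        ("o2", -UB, UB),
        ("co2", -UB, UB),
        ("h2o", -UB, UB),
        ("h", -UB, UB),
        ("nh3", -UB, UB),
        ("n2", -UB, UB),
        ("ala", 0.0, UB),
        ("h2", 0.0, UB),
    ]:
        b.exchange(base, lb, ub)

    for base in C4_DICARBOXYLATES:
        b.rxn(
            f"DCT_{base}",
            {f"{base}_e": -1, "h_e": -1, f"{base}_c": 1, "h_c": 1},
            gene="bg_dctA", name=f"{base} H+ symport", subsystem="transport",
        )
    b.rxn("GLCT", {"glc_e": -1, "glc_c": 1}, gene="bg_glcT",
          name="glucose uptake", subsystem="transport")
    b.rxn("TRIOSET", {"triose_e": -1, "triose_c": 1}, gene="bg_sugT",
          name="triose uptake", subsystem="transport")
    if cfg.include_sucrose_bacteroid_path:
        b.rxn("SUCRT", {"sucr_e": -1, "sucr_c": 1}, gene="bg_sucT",
              name="sucrose uptake", subsystem="transport")
        b.rxn("SUCRCAT", c({"sucr": -1, "h2o": -1, "triose": 4}), gene="bg_sucH",
              name="sucrose hydrolysis", subsystem="sugar metabolism")
    for base in ("o2", "co2", "h2o", "n2", "h2"):
        b.diffusion(base)
    b.rxn("NH3T", {"nh3_e": -1, "nh3_c": 1}, bounds=(-UB, UB),
          name="ammonia diffusion", subsystem="transport")
    b.rxn("ALAT", {"ala_c": -1, "ala_e": 1}, bounds=(-UB, UB),
          name="L-alanine transport", subsystem="transport")
    # passive proton uniport; in the holobiont the boundary side is the PBS,
    # whose only proton source is the plant pump, so proton access still
    # gates all proton-consuming bacteroid chemistry
    b.rxn("HT", {"h_e": -1, "h_c": 1}, bounds=(-UB, UB),
          name="proton uniport", subsystem="transport")

    b.rxn("GLCCAT", c({"glc": -1, "triose": 2}), gene="bg_glk",
          name="glucose cleavage to triose", subsystem="sugar metabolism")
    gap_to_pep = {"triose": -1, "pi": -1, "nad": -1, "pep": 1, "nadh": 1, "h2o": 1, "h": 2}
    b.rxn("GLYC", c(_combine((1, gap_to_pep), (1, ATP_SYNTH))), gene="bg_gapdh",
          name="glycolysis triose->PEP", subsystem="glycolysis")
    b.rxn("PYK", c({"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1}), gene="bg_pyk",
          name="pyruvate kinase", subsystem="glycolysis")
    b.rxn("ME", c({"mal": -1, "nad": -1, "pyr": 1, "co2": 1, "nadh": 1}), gene="bg_dme",
          name="malic enzyme", subsystem="TCA")
    b.rxn("MDH", c({"mal": -1, "nad": -1, "oaa": 1, "nadh": 1, "h": 1}), gene="bg_mdh",
          bounds=(-UB, UB), name="malate dehydrogenase", subsystem="TCA")
    b.rxn("FUMHYD", c({"mal": -1, "fum": 1, "h2o": 1}), gene="bg_fumC",
          bounds=(-UB, UB), name="fumarase", subsystem="TCA")
    b.rxn("SDH", c({"succ": -1, "nad": -1, "fum": 1, "nadh": 1, "h": 1}), gene="bg_sdh",
          name="succinate dehydrogenase", subsystem="TCA")
    b.rxn("PYROX", c({"pyr": -1, "h2o": -3, "nad": -5, "co2": 3, "nadh": 5, "h": 4}),
          gene="bg_pdh", name="pyruvate oxidation (PDH + TCA lump)", subsystem="TCA")
    b.rxn("AKGSYN",
          c({"pyr": -1, "oaa": -1, "h2o": -1, "nad": -2, "akg": 1, "co2": 2,
             "nadh": 2, "h": 1}),
          gene="bg_gltA", name="2-oxoglutarate synthesis", subsystem="TCA")
    b.rxn("OXIDASE", c(_combine((1, NADH_OX), (y, ATP_SYNTH))),
          gene="bg_ctaD and bg_atpA",
          name="terminal oxidase + ATP synthase", subsystem="respiration")
    nitrogenase_core = {"n2": -1, "nadh": -4, "h": -4, "nh3": 2, "h2": 1, "nad": 4}
    b.rxn(
        "NITROGENASE",
        c(_combine((1, nitrogenase_core), (cfg.nitrogenase_atp_per_n2, ATP_HYD))),
        gene="bg_nifH and bg_nifD",
        name="nitrogenase (8 e- as 4 NADH)", subsystem="nitrogen fixation",
    )
    b.rxn("AMT", c({"nh4": -1, "nh3": 1, "h": 1}), bounds=(-UB, UB),
          name="ammonium/ammonia equilibrium", subsystem="nitrogen")
    b.rxn("GS", c({"glu": -1, "nh4": -1, "atp": -1, "gln": 1, "adp": 1, "pi": 1, "h": 1}),
          gene="bg_glnA", name="glutamine synthetase", subsystem="nitrogen")
    b.rxn("GOGAT", c({"gln": -1, "akg": -1, "nadh": -1, "h": -1, "glu": 2, "nad": 1}),
          gene="bg_gltB", name="glutamate synthase", subsystem="nitrogen")
    b.rxn("ALAAT", c({"pyr": -1, "glu": -1, "ala": 1, "akg": 1}), gene="bg_alaAT",
          bounds=(-UB, UB), name="alanine transaminase", subsystem="nitrogen")
    b.rxn("PREC1SYN", c(_combine((1, {"pyr": -3, "prec1": 1}), (6, ATP_HYD))),
          gene="bg_anab1", name="carbon-skeleton precursor synthesis",
          subsystem="anabolism")
    b.rxn("PREC2SYN", c(_combine((1, {"ala": -2, "prec2": 1}), (4, ATP_HYD))),
          gene="bg_anab2", name="amino precursor synthesis", subsystem="anabolism")
    b.rxn(
        "BIOMASS",
        c(_combine(
            (1, {"prec1": -2500 * s, "prec2": -900 * s, "biomass": 1}),
            (15000 * s, ATP_HYD),
        )),
        gene="bg_bio", name="bacterial biomass", subsystem="biomass",
    )
    b.rxn("NGAM", c(ATP_HYD), bounds=(0.0, MAINT_UB),
          name="non-growth-associated maintenance", subsystem="maintenance")
    b.rxn("DM_biomass", {"biomass_c": -1}, name="biomass demand", subsystem="biomass")
    _add_decoys(b, rng, cfg.decoy_reaction_count // 2, "bg")
    b.model.objective = "BIOMASS"
    return b.model


# ---------------------------------------------------------------------------
# expression calls


@dataclass
class ExpressionCallSet:
    """zone tag -> gene id -> on/off; genes not listed default to on."""

    calls: dict[str, dict[str, bool]] = field(default_factory=dict)

    def is_on(self, zone: str, gene: str) -> bool:
        return self.calls.get(zone, {}).get(gene, True)

    def off_genes(self, zone: str) -> set[str]:
        if zone not in self.calls:
            raise KeyError(f"no expression calls for zone {zone!r}")
        return {g for g, on in self.calls[zone].items() if not on}

    def zones(self) -> list[str]:
        return sorted(self.calls)

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            {"zone": z, "gene": g, "call": "on" if on else "off"}
            for z in sorted(self.calls)
            for g, on in sorted(self.calls[z].items())
        ]
        pd.DataFrame(rows, columns=["zone", "gene", "call"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "ExpressionCallSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        calls: dict[str, dict[str, bool]] = {}
        for row in df.itertuples(index=False):
            calls.setdefault(row.zone, {})[row.gene] = row.call == "on"
        return cls(calls)


PLANT_ZONES = ["Shoot", "Root", "NoduleI", "NoduleIId", "NoduleIIp", "NoduleIZ", "NoduleIII"]
BACTEROID_ZONES = ["BacteroidIId", "BacteroidIIp", "BacteroidIZ", "BacteroidIII"]
NODULE_ZONE_NAMES = ["IId", "IIp", "IZ", "III"]


def generate_zone_calls(
    config: ToyConfig, plant: Model, bacterium: Model
) -> ExpressionCallSet:
    """Zone-wise on/off calls implementing the nodule developmental logic.

    Nitrogenase genes are on only in the zone III bacteroid; bacterial
    biomass-pathway genes are off in zone III (terminally differentiated
    bacteroids do not grow); the plant biomass gene is off in zone III tissue;
    everything else is on in zones I-IZ; decoy genes are off everywhere.
    Zone I has no bacterial entry (the meristem is bacterium-free).
    """
    plant_genes = {g.id for g in plant.genes}
    bact_genes = {g.id for g in bacterium.genes}
    plant_decoys = {g for g in plant_genes if "_dec" in g}
    bact_decoys = {g for g in bact_genes if "_dec" in g}
    nif_genes = {"bg_nifH", "bg_nifD"} & bact_genes
    bact_biomass_pathway = {"bg_bio", "bg_anab1", "bg_anab2"} & bact_genes
    unknown = (nif_genes | bact_biomass_pathway) - bact_genes
    if unknown:
        raise ValueError(f"genes missing from bacterium model: {sorted(unknown)}")

    calls: dict[str, dict[str, bool]] = {}
    for zone in PLANT_ZONES:
        zone_calls = {g: False for g in plant_decoys}
        if zone == "NoduleIII":
            zone_calls["pg_bio"] = False
        calls[zone] = zone_calls
    for zone in BACTEROID_ZONES:
        zone_calls = {g: False for g in bact_decoys}
        if zone == "BacteroidIII":
            for g in bact_biomass_pathway:
                zone_calls[g] = False
        else:
            for g in nif_genes:
                zone_calls[g] = False
        calls[zone] = zone_calls
    return ExpressionCallSet(calls)


def generate_toy_holobiont_inputs(config: ToyConfig | None = None):
    """Convenience bundle: (plant, bacterium, calls) for one config."""
    cfg = config or ToyConfig()
    plant = generate_toy_plant(cfg)
    bacterium = generate_toy_bacterium(cfg)
    calls = generate_zone_calls(cfg, plant, bacterium)
    return plant, bacterium, calls


def set_ngam(model: Model, rate: float) -> None:
    """Force non-growth maintenance ATP hydrolysis at *rate* (lower bound)."""
    rxn = model.reactions.get_by_id("NGAM" if model.reactions.has_id("NGAM") else "ATPM")
    rxn.lower_bound = rate
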