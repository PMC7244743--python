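# Methods

## The holobiont model

The package builds one stoichiometric model of a nodulated legume from two
single-organism reconstructions. The plant model is replicated into seven
tissues (`Shoot`, `Root`, `NoduleI`, `NoduleIId`, `NoduleIIp`, `NoduleIZ`,
`NoduleIII`), every metabolite/reaction/gene/compartment id prefixed with its
tissue tag. The bacterium is replicated into four bacteroid tissues
(`BacteroidIId/IIp/IZ/III`); its boundary compartment becomes a peribacteroid
space (`PBS_<zone>`) and its environment exchanges are replaced by
plant↔PBS transfer reactions. All fluxes are µmol h⁻¹ per g total plant dry
weight; biomass drains are g biomass h⁻¹ gDW⁻¹ (growth is also reported
per day, ×24).

**Objective.** A single drain reaction consumes the nine tissue-biomass
species at fixed weights (shoot 0.65333, root 0.32666, nodule zones
0.00100/0.00675/0.00225/0.00675/0.00225/0.00075/0.00025; zone III carries no
biomass term — it is maintained, not grown). Encoding the proportions
stoichiometrically, rather than as a weighted linear objective over
independent biomass reactions, is what forces the model to *co-produce* all
tissues at the stated composition; a weighted objective would let the LP
grow shoot only. For a general nodulation fraction f, shoot/root carry
(1−f) at the 2:1 ratio truncated to five decimals (which reproduces the
reference constants exactly at f = 0.02, total 0.99999) and zone weights
scale by f/0.02.

**Nodulation rescaling.** `rescale_nodulation(f)` keeps only shoot/root in
the objective (2/3, 1/3) and makes the same drain co-consume the nodule and
bacteroid biomass species at f/(1−f) times their default internal
proportions — a nodule-biomass sink ratio-locked to plant growth. Nodule and
bacteroid maintenance bounds and the zone III O₂ cap scale linearly in
f/0.02. At f = 0.02 this reproduces the default build's growth exactly; at
f = 0 it reduces to a nodule-free plant. Because f enters the constraint
matrix (not only right-hand sides), the growth-vs-f curve is unimodal and
piecewise-smooth but not exactly concave; the inner 1-D maximisations over f
therefore use golden-section search (tolerance 10⁻⁴), which is exact for
unimodal curves.

**Constraints.** Light and CO₂ enter at the shoot (1000 µmol h⁻¹ gDW⁻¹
each); nitrate/ammonium enter only at the root and are closed under N₂-only
nitrogen (export of surplus ammonium stays open); every tissue exchanges
O₂/CO₂/water/protons; nodule zones exchange N₂ (in) and H₂ (out); zone III
tissue O₂ uptake is capped at 8.9847 µmol h⁻¹ gDW⁻¹. Maintenance is a
forced lower bound on a per-tissue ATP-hydrolysis reaction: shoot 74, root
37 µmol h⁻¹ gDW⁻¹; plant nodule zones I/IId/IIp/IZ/III 0.111/0.750/0.750/
0.083/0.833; bacteroids IId/IIp/IZ/III 5.7/5.7/0.6/6.3. Single-metabolite
diffusion between compartments costs 0.25 mol ATP per mol in the source
tissue. Zone III bacteroids may import only succinate/malate/fumarate
(≤1000 each); other zones are not carbon-restricted.

**Peribacteroid space and proton access.** Dicarboxylates enter bacteroids
by H⁺ symport (one external proton per molecule). The only proton source in
the PBS is an ATP-driven plant pump (2 H⁺ per ATP, V-ATPase-like; a relief
valve lets surplus PBS protons drain back to the plant but never supplies
them). Setting `bacteroid_proton_access=False` omits the pump, which starves
the symporters and — because zone III bacteroid maintenance is still
forced — renders the build infeasible under *any* nitrogen source, not just
N₂-only. The pump ratio matters for the oxidase titration (below): at 2
H⁺/ATP the plant's fermentative sucrose→dicarboxylate route is marginally
ATP-positive, so a capped zone III oxidase forces carbon through
fermentation (dicarboxylate delivery) without making zone III insolvent.

**Expression gating.** A reaction is closed (both bounds 0) in a zone copy
iff its gene rule is non-empty and evaluates false with the zone's off-genes
inactive; reactions without gene rules (exchanges, transport, spontaneous
chemistry) are never gated. Gating is exact OR-of-ANDs evaluation, monotone
and idempotent. `call_from_abundance` provides a quantile rule (gene on iff
abundance ≥ the given quantile of the zone's nonzero abundances) for users
starting from abundance tables; the shipped generator emits binary calls
directly.

**Dead-end pruning.** After gating, reactions closed to zero flux are
dropped, then reactions touching metabolites that are only produced or only
consumed (reversible reactions count on both sides; exchanges count as
ordinary producers/consumers) are removed iteratively to the unique
fixpoint. Reactions carrying objective weight are protected (pruning one is
an error, not a silent removal).

## The miniature organism pair

The generator emits a deterministic desk-scale plant and rhizobium carrying
exactly the structure the analysis assumes (see the module docstring of
`nodulefba.toy` for the pathway inventory). Design choices:

* Every internal reaction is element- and charge-balanced, built from real
  elemental formulas; ATP synthesis is the condensation ADP + Pi + H⁺ →
  ATP + H₂O and appears only folded into driven reactions (glycolytic
  substrate-level steps, the terminal oxidases), never free-standing — so
  there are no energy leaks: with maintenance forced and no carbon source,
  the models are infeasible.
* Redox is carried by a single NAD(H) pool. Respiration is lumped:
  NADH + H⁺ + ½O₂ → NAD⁺ + H₂O plus P/O × (ATP synthesis), with P/O = 2.5
  (`o2_per_atp_respiration = 0.2`), the modern consensus value.
* Nitrogenase is N₂ + 8 H⁺ + 8 e⁻ (as 4 NADH) + 16 ATP → 2 NH₃ + H₂ with
  the textbook 16 ATP default (`nitrogenase_atp_per_n2` is configurable).
* Biomass reactions are short weighted sums (µmol-scale precursors per g):
  plant 9000 triose + 1700 alanine + 30000 ATP; bacterium 2500 C-skeleton
  precursor + 900 amino precursor + 15000 ATP, the precursors made by two
  gene-gated anabolic steps so "biomass pathway off" closes more than one
  reaction. The amino-acid lump is L-alanine, which doubles as the
  alternative nitrogen export product.
* Zone calls: nitrogenase on only in the zone III bacteroid; bacterial
  biomass-pathway genes off in zone III; the plant biomass gene off in zone
  III tissue; everything on in zones I–IZ; seeded random decoy reactions
  (structural dead ends) off everywhere. The meristem (zone I) carries no
  bacteria.
* The default transport table: sucrose shoot→root→all zones (with the 0.25
  ATP cost); reversible ammonium links root↔shoot and root↔each zone (fixed
  nitrogen flows out of zone III, and differentiation zones draw nitrogen
  for their own and their bacteroids' growth); reversible no-cost NH₃ and
  alanine plant↔PBS transfers; a triose transfer into non-III PBS
  compartments as the proton-independent "sugar" carbon source for
  differentiation-zone bacteroids (zone III remains dicarboxylate-only).

The seed only shuffles the decoy reactions; the metabolic core, and hence
every reported quantity, is seed-invariant.

**Operating point.** With the fixed constraint set (zone III O₂ cap, 16
ATP/N₂, bacteroid maintenance), the maximum supportable fixation efficiency
on the miniature system is ≈115 µmol h⁻¹ per g nodule — the O₂ cap times the
ATP yield per O₂ divided by the nitrogenase ATP demand — and is independent
of the nodulation fraction (nitrogenase flux and the O₂ cap both scale
linearly in f). The full-scale system's conventional constant-efficiency
setting of 150 lies above this bound, so the constant-efficiency experiments
here use the miniature system's documented operating point of **100**
(near its Pareto optimum); the function defaults keep 150 for use with
genome-scale inputs.

## What the miniature system does and does not show

Passing tests demonstrate the *mechanisms*: obligate coupling of plant
growth to zone III fixation; essentiality of nitrogenase and dicarboxylate
transport and dispensability of bacterial glutamine synthetase; the
proton-access requirement for dicarboxylate-fed fixation; O₂-cap-driven
collapse just past the Pareto-optimal efficiency (≈10% excess) versus graded
decline without the cap; the steeper-below-than-above nodulation trade-off;
the ordering of the SNF cost decomposition (fixation energy > maintenance >
synthesis); and the oxidase-limited switch from sucrose to dicarboxylates as
the bacteroid carbon source. Quantities tied to network size or real biomass
composition (absolute growth rates, the exact 3-fold slope ratio, exact
reaction counts per zone) are *not* expected to match a genome-scale
reconstruction, and the tests assert shapes, orderings and oracle agreement
rather than those magnitudes. When users supply full-scale SBML
reconstructions, the same entry points (`read_model`, `build_holobiont`,
`experiments.*`) run unchanged.

## Numerical choices

GLPK via optlang; LP feasibility/optimality at solver defaults (~10⁻⁹);
flux-zero threshold 10⁻⁹; balance tolerance and all objective comparisons
10⁻⁶. Reported flux routes (e.g. the sucrose/dicarboxylate split) come from
parsimonious FBA (minimise Σ|v| at ≥99.99% of the optimum) because raw FBA
flux vectors are degenerate; objective values use plain FBA. Robustness
scans bracket the nonzero-growth flux interval by bisection (tolerance 10⁻⁴
of the range) before gridding. Infeasible scan points are recorded with
growth 0 and their solver status. Reaction classification: *inactive* iff
the FVA range at ≥99% optimum is {0}; *central* iff single-zone removal cuts
plant growth by >10%; for the differentiation super-zone, central requires
central in each of IId, IIp and IZ. Double gene deletions are global-scope
only.

## Known limitations

* The miniature networks are not reductions of any real reconstruction;
  pathway lumping (single NAD pool, one-step TCA lump, photon-light
  photosynthesis) hides redox shuttling and compartmental detail.
* Binary expression calls only; no continuous expression integration.
* The proton/charge bookkeeping of the peribacteroid membrane is reduced to
  one pump + one symport family + a relief valve; no membrane potential.
* No gap-filling, no thermodynamic constraints, no O₂ diffusion physics;
  the zone III O₂ cap is a single number, not a geometry.
* `HolobiontSpec` maintenance scaling with f is linear by assumption.
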