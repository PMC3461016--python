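# Methods

This note documents the modeling choices behind `memodel`: what is
represented, which parameters matter, what the synthetic fixtures do and do
not emulate, and where the design was genuinely open.

## Scope of the representation

The model couples two reconstruction layers over one stoichiometric matrix:

* **Metabolic layer** — reactions over small metabolites in compartments
  c/p/e, with exchange reactions supplying the medium (substrates negative,
  products positive; fluxes in mmol·gDW⁻¹·h⁻¹, the standard COBRA unit).
* **Expression layer** — species and reactions for mRNAs, proteins,
  complexes, charged/uncharged tRNAs, rRNA and ribosomes, generated from
  gene sequences (1-based inclusive coordinates, GenBank convention).

Transcription is lumped to one initiation plus one elongation reaction per
transcription unit rather than per-nucleotide chains: the unit-level
granularity is what the coupling layer and the transcription caps act on,
and sub-step templates add size without changing any quantity this package
computes. Polycistronic transcripts are cleaved stoichiometrically into one
mRNA per member gene. Protein folding is collapsed into a single
spontaneous-folding path; chaperone species can be declared in complex
specifications but no folding-partition model is implemented. Protein
secretion mechanisms are not modeled; enzymes reach the periplasm or
extracellular space through one or two explicit export reactions.

## Enzyme-explicit metabolic units

Each GPR-carrying metabolic reaction becomes, per isozyme module and per
direction: activation (ENZ → ENZ_active), catalysis (substrates +
ENZ_active → products + ENZ_inactive), recycling (`_DREC`) and one shared
enzyme demand (`DM_…`) — 4 reactions for an irreversible reaction, 7 for a
reversible one, with direction-specific enzyme pools. This scheme was
chosen among the possible three-reaction decompositions because it (a)
conserves enzyme mass exactly (one activation+catalysis+recycle cycle nets
the bare metabolic conversion), (b) reproduces the 4-and-7 unit counts, and
(c) exposes a single demand flux per enzyme for the coupling layer to latch
onto. Isozymes get independent units and demands; AND modules first form a
complex (all subunits binding in one composite reaction, one metallo-ion
per monomer when counts are unknown, monomeric enzymes when no complex
information exists). Reactions without a GPR pass through unexpanded;
associations to the artificial gene `s0001` are dropped, and tRNA-charging
reactions in the metabolic input are removed before integration because the
expression layer regenerates them from the recognition map.

## Coupling constraints

Each coupling (v_syn, v_use, c_min, c_max) adds

    v_use − c_max·v_syn ≤ 0
    c_min·v_syn − v_use ≤ 0        (omitted when c_min = 0)

i.e. the utilization/synthesis ratio is confined to [c_min, c_max]. This is
the simplest linear form with the three required behaviors: zero synthesis
forces zero use; raising use raises the minimum feasible synthesis
(min v_syn = v_use/c_max); and a small c_min permits synthesis beyond use —
accumulation, carried by the demand reaction. Both rows are stored
explicitly so alternative algebraic forms can be swapped without touching
callers.

Three coupling families are attached by the builder:

* **mRNA → translation**, per protein gene, between `<locus>_mRNA_degr1`
  (synthesis-side: at steady state degradation equals transcription, since
  the `_CONV2` cycling reaction returns used mRNA to the pool) and
  `tl_ini_<locus>`. Coefficients are k·t½/L — translations one transcript
  supports before turnover — evaluated at the half-life bounds t½ ∈
  [0.1, 60] min with k = 12 aa/s and L the protein length. The mRNA pool is
  thus maintained, not accumulated: transcription flux is pool maintenance.
* **Enzyme demand → catalysis**, per metabolic unit, between `DM_<enz>` and
  each `_DREC` flux, with (c_min, c_max) = (1, 10000): one enzyme dilution
  event supports up to 10⁴ catalytic turnovers. c_max is deliberately large
  because metabolic fluxes exceed synthesis fluxes by orders of magnitude.
* **tRNA transcription → charging**, per tRNA species, with c_max = 1000
  turnovers per tRNA synthesized (c_min = 0). This is the constraint that
  makes tRNA supply a finite, cappable resource.

Ribosome capacity is represented stoichiometrically rather than by a
coupling row: one translation event consumes a configurable fraction
(default 10⁻³) of a ribosome, i.e. a ribosome survives ~1000 translations
before dilution. A pairwise coupling cannot bound the *sum* of all
translation fluxes, while a consumed pool species does exactly that; the
default single-ribosome-per-mRNA accounting can be scaled up via a density
multiplier. The combination of nucleotide-count coefficients (~10²),
unit-scale metabolism and 10⁻³-scale ribosome usage spreads coefficients
over ≥4 orders of magnitude — the multiscale signature (mini-coli spans
~10⁶·²) — which is why every solve can be re-verified and a geometric-mean
column rescaling retry backs the solver. The advanced LP lifting techniques
for genuinely genome-scale ME problems are out of scope; simple scaling
plus explicit tolerance verification is implemented instead.

## Biomass, media, caps

The biomass reaction carries tagged amino-acid terms and a tagged
growth-associated maintenance (GAM) ATP hydrolysis. Because the expression
layer already pays amino acids and energy for the modeled gene products,
both tags can be scaled (`adjust_biomass`); scaling acts multiplicatively
on current coefficients so adjustments compose, and NTP terms are never
touched (their biomass contribution is small). Non-growth-associated
maintenance (ATPM) is a configurable lower bound, default 0 in the toy
fixtures so knockout lethality reads as zero growth rather than
infeasibility. Media are exchange-bound dictionaries; a base-medium list of
18 freely taken ions is shipped for genome-scale conventions (default free
uptake 1000, default carbon uptake 10 mmol·gDW⁻¹·h⁻¹).

Transcription-initiation caps are rate·3600/length·dosage with polymerase
rates 85 nt/s (stable RNA) and 55 nt/s (mRNA), corresponding to fast growth
(24 min doubling), with per-TU overrides.

## Gene deletions

A knockout zeroes the gene's translation-initiation bounds and removes the
coupling rows referencing the gene's synthesis/usage reactions (deleting a
gene inside an operon must not silence its co-transcribed neighbours, which
shared coupling rows would do). Removal alone, however, would reopen the
enzyme cycle the couplings governed, so the default `local` mode also
forces the metabolic-unit reactions of enzymes *requiring* the locus to
zero — no synthesis, no catalysis — while isozyme-backed units stay open. A
`literal` remove-only mode is provided for comparison. Essentiality is
growth < 5% of wildtype (configurable; no canonical threshold exists).

## Codon-usage evolution

Synonymous-codon Shannon entropy weights each amino acid's family entropy
by its count: H = (1/N)·Σₐ nₐ·(−Σ_c p_{a,c}·ln p_{a,c}), in nats, with
0·ln 0 = 0, probabilities from the gene's own codon counts, the start codon
counted as its literal codon and stops excluded; the genome value is the
mean over genes, making strains comparable.

The *biased* generator performs m = 100 iterations of: draw a random sense
codon c₁, draw a synonymous c₂ ≠ c₁ (a self-swap would be a no-op; a
strict-literal mode allowing c₂ = c₁ exists), and replace every internal
instance of c₁ across all protein genes. The *equilibrated* generator
re-initializes a global codon counter each pass, walks the genes in a fresh
random order and assigns every internal codon the family member with the
lowest current count (lexicographic tie-break; a seeded-random tie-break is
available), leveling family counts to within 1. Start and stop codons are
immutable in both generators and excluded from the counter, so translated
protein sequences are invariant by construction. The standard experiment
preset is 10 biased + 5 equilibrated strains with distinct seeds.

A strain model is rebuilt from the perturbed genome with the stored builder
configuration: transcription NTP demands, degradation NMP releases and
translation tRNA choices are regenerated while reaction/species id sets,
bounds and couplings stay exactly the wildtype's — only coefficients move.

## The synthetic fixtures

`mini_coli` is the canonical fixture (~34 genes; full build+solve well
under a second, so the whole suite runs in seconds): 12 protein genes in
2-gene TUs over a 10-amino-acid alphabet, a glucose→energy/precursor→
biomass metabolic core exercising single-gene, isozyme (OR), complex (AND,
with a zinc ion) and reversible cases, 21 tRNA genes covering a generic
recognition map, and one rRNA gene. Three constructed features matter:

* Codon preferences are uniform within families except CTA (weight 0),
  mirroring the rarity of that leucine codon in fast-growing bacteria, and
  the leucine family is split between a major species (tRNA_Leu1) and a
  single-codon minor species (tRNA_Leu2 reading CTA). Recoding the family
  onto CTA therefore funnels all leucine demand through one cappable tRNA.
* The rRNA TU cap defaults to 2·10⁻⁶ initiations/h, chosen so ribosome
  supply — not carbon — limits growth at the default glucose uptake; this
  gives reduced-cost analyses a binding, growth-limiting bound by
  construction.
* The fixture verifies its own feasibility (positive growth) at build time
  and retries with a bumped seed on failure.

What the toys do **not** emulate: realistic genome composition or length
distributions, operon structure beyond simple contiguity, compartmentalized
metabolism, regulatory constraints, and the absolute magnitudes of a
genome-scale reconstruction. Passing tests therefore demonstrate the
mechanisms (coupling logic, bottleneck formation, entropy ordering,
deletion semantics), not quantitative agreement with any real organism.

## Numerical choices

* LP: HiGHS (scipy.optimize.linprog); infeasible and unbounded states are
  reported distinctly; on numerical failure, a geometric-mean column
  scaling is applied and the solve retried, with primal and dual quantities
  mapped back to the original scale.
* Every solution can be verified against |S·v| ≤ tol, bound and coupling
  violations (default tol 10⁻⁶).
* Reduced costs are reported as ∂(objective)/∂(bound); rankings break ties
  by reaction id for reproducibility, and zero lower bounds
  (irreversibility) are excluded from bottleneck reports by default since
  "relaxing" them has no physical meaning.
* All randomness flows through numpy Generators seeded explicitly;
  identical seeds give byte-identical strains, fixtures and models.

## Known limitations

Single-chromosome genomes without overlap or splicing; no rRNA/tRNA
modification chemistry beyond single-step maturation; transcription
regulation reactions exist only as unconstrained placeholders; knockouts
are defined for protein-coding genes only; the reverse direction of a
reversible unit keeps its own inactive-enzyme pool (whether the pools
should be shared is not determinable from first principles; separate pools
keep directions independently cappable).
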