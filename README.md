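# memodel

Multiscale **metabolism-and-expression (ME) modeling** in Python: build
constraint-based models in which the macromolecular machinery that expresses
every enzyme — transcription, mRNA turnover, tRNA charging, translation,
complex assembly — is itself part of the stoichiometric network, at single
nucleotide resolution, and use them to study how genome sequence (in
particular codon usage) constrains growth.

The package is aimed at systems biologists working with genome-scale
metabolic models who want to go beyond metabolism-only flux balance
analysis (FBA): every gene product used by the network must also be
synthesized by it, paying the real NTP, amino-acid, GTP and ATP costs of its
own sequence.

## The model

An ME model is an ordinary FBA problem

&nbsp;&nbsp;&nbsp;&nbsp;max μ  s.t.  S·v = 0, lb ≤ v ≤ ub

extended with two ingredients:

1. **Sequence-specific synthesis reactions.** For each transcription unit
   (TU) a lumped transcription reaction consumes exactly the transcript's
   NTP letter counts and releases one PPi per nucleotide; per-gene mRNA
   degradation releases the matching NMPs; translation consumes, per codon,
   one charged tRNA chosen by a tRNA→codon recognition map (generic species
   standing for isoacceptor families) plus GTP, and returns the uncharged
   tRNAs. Each metabolic reaction with a gene-protein-reaction (GPR) rule is
   replaced by an enzyme-explicit *metabolic unit* — activation, catalysis,
   recycling (`_DREC`) and enzyme demand (`DM_…`) — 4 reactions when
   irreversible, 7 when reversible; OR rules give independent isozyme units,
   AND rules a complex-formation reaction (one metallo-ion per monomer when
   the stoichiometry is unknown).

2. **Coupling constraints.** Synthesis and utilization fluxes are tied by
   linear inequality pairs
   `v_use ≤ c_max·v_syn` and `c_min·v_syn ≤ v_use`,
   so a component can only be used if it is synthesized, and higher use
   forces more synthesis. mRNA→translation coefficients derive from
   `k_translation·t½/L` with the mRNA half-life bounded to [0.1, 60] min;
   enzyme demand→catalysis uses (c_min, c_max) = (1, 10000).

On top of the solver (HiGHS via scipy, with numerical verification of every
solution against `|S·v| ≤ tol`), the package provides reduced-cost
bottleneck reports, single-gene deletion and media screens, biomass
amino-acid/GAM sensitivity scans, and the codon-usage evolution toolkit:
amino-acid-weighted synonymous-codon Shannon entropy, *biased* strains
(random genome-wide synonymous codon collapses) and *equilibrated* strains
(greedy leveling of global codon counts), both provably protein-neutral,
plus strain→model rebuilds that change only stoichiometric coefficients.

## Worked example

```python
import memodel as M

fx = M.mini_coli(seed=1)                 # ~34-gene toy organism, full ME model
sol = M.solve_fba(fx.model)
print(sol.objective_value)               # 0.6507609806294782  (growth, 1/h)
print(M.verify_solution(fx.model, sol).passed)   # True

print(M.reduced_cost_report(fx.model, sol, top_k=1))
#             reaction_id bound   reduced_cost
# 0  tscr_iniTU_rrna_stab    ub  325380.490315
```

Growth is limited by the rRNA transcription cap (the ribosome supply), and
the reduced-cost report finds exactly that bound; doubling the cap raises
growth to 1.2499 1/h. Recoding the entire leucine family onto CTA — read
only by the minor species tRNA_Leu2 whose transcription unit is capped —
collapses growth ~600-fold while leaving the wildtype untouched:

```python
wt_capped, strain_model, capped_id = M.trna_bottleneck(fx)
M.solve_fba(wt_capped).objective_value      # 0.6507609806294782 (unchanged)
M.solve_fba(strain_model).objective_value   # 0.0010693474447880488
M.reduced_cost_report(strain_model, M.solve_fba(strain_model), top_k=1)
#                  reaction_id bound   reduced_cost
# 0  tscr_iniTU_trna_leu2_stab    ub  106934.744479
```

Codon-usage perturbations order by synonymous-codon entropy exactly as
expected — biased < wildtype < equilibrated:

```python
H = lambda g: M.shannon_entropy(
    {x.locus_id: g.gene_sequence(x.locus_id) for x in g.protein_genes()}).total
H(fx.genome)                                                        # 0.6469
H(M.generate_biased_strain(fx.genome, m=100, seed=3).genome)        # 0.1015
H(M.generate_equilibrated_strain(fx.genome, m=5, seed=3).genome)    # 0.8517
```

A thin CLI wraps the same functions: `memodel fixtures`, `memodel solve`,
`memodel knockout`, `memodel screen`, `memodel evolve`.

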