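"""Codon-usage-bias (CUB) experiments: synonymous-codon Shannon entropy,
biased and equilibrated in silico strain generators, strain-to-model
rebuilds and effective codon usage.

Both strain generators perform synonymous substitutions only, never touch
start or stop codons, and leave every translated protein sequence identical
to wildtype — only the stoichiometric coefficients of the rebuilt model
change, never its reaction or species sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CodonTable, Genome, split_codons, standard_codon_table

__all__ = [
    "StrainVariant",
    "EntropyResult",
    "shannon_entropy",
    "generate_biased_strain",
    "generate_equilibrated_strain",
    "recode_family",
    "rebuild_strain_model",
    "make_strain_library",
    "effective_codon_usage",
    "correlate",
]


@dataclass
class StrainVariant:
    """A genome perturbed in codon usage, with full provenance."""

    label: str
    genome: Genome
    algorithm: str
    m: int
    seed: int | None
    swaps: list[tuple] = field(default_factory=list)


@dataclass
class EntropyResult:
    per_gene: pd.Series  # nats, indexed by locus
    total: float  # mean over genes

    def __float__(self) -> float:
        return self.total


# ---------------------------------------------------------------------------
# Entropy


def _gene_entropy(codons: list[str], ct: CodonTable) -> float:
    """Amino-acid-weighted synonymous codon entropy of one coding sequence.

    H = (1/N) * sum_a n_a * ( -sum_c p_{a,c} ln p_{a,c} ), with p taken from
    this gene's own codon counts and 0*ln(0) = 0.  Single-codon amino acids
    contribute zero.  The start codon counts as its literal codon; the stop
    codon is excluded.
    """
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    by_aa: dict[str, dict[str, int]] = {}
    for c, n in counts.items():
        by_aa.setdefault(ct.forward[c], {})[c] = n
    N = len(codons)
    total = 0.0
    for aa, fam_counts in by_aa.items():
        n_a = sum(fam_counts.values())
        h_a = 0.0
        for c in ct.synonymous_family(next(iter(fam_counts))):
            p = fam_counts.get(c, 0) / n_a
            if p > 0:
                h_a -= p * math.log(p)
        total += n_a * h_a
    return total / N


def shannon_entropy(
    gene_sequences: dict[str, str], codon_table: CodonTable | None = None
) -> EntropyResult:
    """Per-gene synonymous codon entropy (nats) and the genome mean.

    The genome-level value is the mean of per-gene entropies (total entropy
    divided by the number of genes), making strains of different bias
    directly comparable.
    """
    ct = codon_table or standard_codon_table()
    per_gene = {}
    for locus, seq in sorted(gene_sequences.items()):
        codons = split_codons(seq)
        if codons[-1] in ct.stop_codons:
            codons = codons[:-1]
        bad = [c for c in codons if c not in ct.forward]
        if bad:
            raise ValueError(f"{locus}: unreadable codons {bad}")
        per_gene[locus] = _gene_entropy(codons, ct)
    s = pd.Series(per_gene, dtype=float)
    return EntropyResult(s, float(s.mean()))


# ---------------------------------------------------------------------------
# Strain generation helpers


def _protein_codon_lists(genome: Genome) -> dict[str, list[str]]:
    return {
        g.locus_id: split_codons(genome.gene_sequence(g.locus_id))
        for g in genome.protein_genes()
    }


def _write_back(genome: Genome, codon_lists: dict[str, list[str]]) -> Genome:
    """Rebuild the chromosome with perturbed coding sequences (strand-aware)."""
    from .genome import reverse_complement

    seq = list(genome.sequence)
    for locus, codons in codon_lists.items():
        gene = genome.genes[locus]
        cds = "".join(codons)
        if gene.strand == "-":
            cds = reverse_complement(cds)
        seq[gene.start - 1 : gene.end] = cds
    return genome.with_sequence("".join(seq))


def generate_biased_strain(
    genome: Genome,
    m: int = 100,
    seed: int = 0,
    label: str | None = None,
    forced_swaps: list[tuple[str, str]] | None = None,
    allow_self_swap: bool = False,
) -> StrainVariant:
    """Codon-collapsing strain: m random genome-wide synonymous replacements.

    Each iteration draws a random sense codon c1, draws a synonymous c2
    (c2 != c1 unless ``allow_self_swap``, the strict-literal mode) and
    replaces every instance of c1 across all protein genes, excluding start
    and stop positions.  Codons without synonyms (ATG, TGG) are re-drawn and
    the re-draw logged.  ``forced_swaps`` bypasses the random draws (used
    for deterministic worked examples).
    """
    ct = genome.codon_table
    rng = np.random.default_rng(seed)
    codon_lists = _protein_codon_lists(genome)
    sense = ct.sense_codons
    swaps: list[tuple] = []

    if forced_swaps is not None:
        plan = list(forced_swaps)
        m = len(plan)
    else:
        plan = None

    it = 0
    while it < m:
        if plan is not None:
            c1, c2 = plan[it]
        else:
            c1 = sense[rng.integers(len(sense))]
            family = ct.synonymous_family(c1)
            pool = family if allow_self_swap else [c for c in family if c != c1]
            if not pool:
                swaps.append(("redraw", c1))
                continue
            c2 = pool[rng.integers(len(pool))]
        n_replaced = 0
        for codons in codon_lists.values():
            for i in range(1, len(codons) - 1):  # skip start and stop codons
                if codons[i] == c1:
                    codons[i] = c2
                    n_replaced += 1
        swaps.append((c1, c2, n_replaced))
        it += 1

    strain_genome = _write_back(genome, codon_lists)
    return StrainVariant(
        label or f"B_seed{seed}", strain_genome, "biased", m, seed, swaps
    )


def generate_equilibrated_strain(
    genome: Genome,
    m: int = 100,
    seed: int = 0,
    label: str | None = None,
    random_tie_break: bool = False,
) -> StrainVariant:
    """Count-leveling strain: greedy reassignment toward equal codon usage.

    Each pass re-initializes a global codon counter, traverses the protein
    genes in a fresh random order and, at every internal codon position,
    substitutes the synonymous codon with the lowest current global count
    (ties broken lexicographically, or randomly with ``random_tie_break``),
    updating the counter.  Start and stop codons are immutable and do not
    enter the counter.  Repeated m times.
    """
    ct = genome.codon_table
    rng = np.random.default_rng(seed)
    codon_lists = _protein_codon_lists(genome)
    loci = sorted(codon_lists)
    swaps: list[tuple] = []

    for _ in range(m):
        counter = {c: 0 for c in ct.sense_codons}
        order = [loci[i] for i in rng.permutation(len(loci))]
        for locus in order:
            codons = codon_lists[locus]
            for i in range(1, len(codons) - 1):
                family = ct.synonymous_family(codons[i])
                lowest = min(counter[c] for c in family)
                candidates = [c for c in family if counter[c] == lowest]
                chosen = (
                    candidates[rng.integers(len(candidates))]
                    if random_tie_break
                    else candidates[0]
                )
                if chosen != codons[i]:
                    swaps.append((locus, i, codons[i], chosen))
                codons[i] = chosen
                counter[chosen] += 1

    strain_genome = _write_back(genome, codon_lists)
    return StrainVariant(
        label or f"EQ_seed{seed}", strain_genome, "equilibrated", m, seed, swaps
    )


def recode_family(genome: Genome, target_codon: str, label: str | None = None) -> StrainVariant:
    """Collapse a whole synonymous family onto one codon (bottleneck construction).

    Every internal occurrence of any codon synonymous with ``target_codon``
    is replaced by ``target_codon``, concentrating the family's translation
    demand on whichever tRNA species reads it.
    """
    ct = genome.codon_table
    family = set(ct.synonymous_family(target_codon))
    codon_lists = _protein_codon_lists(genome)
    swaps: list[tuple] = []
    for locus, codons in codon_lists.items():
        for i in range(1, len(codons) - 1):
            if codons[i] in family and codons[i] != target_codon:
                swaps.append((locus, i, codons[i], target_codon))
                codons[i] = target_codon
    return StrainVariant(
        label or f"recode_{target_codon}", _write_back(genome, codon_lists),
        "recode_family", 1, None, swaps,
    )


def make_strain_library(
    genome: Genome, n_biased: int = 10, n_equilibrated: int = 5, m: int = 100, base_seed: int = 0
) -> list[StrainVariant]:
    """The standard experiment preset: 10 biased + 5 equilibrated strains, m=100."""
    strains = [
        generate_biased_strain(genome, m=m, seed=base_seed + i, label=f"B{i+1}")
        for i in range(n_biased)
    ]
    strains += [
        generate_equilibrated_strain(genome, m=m, seed=base_seed + 1000 + i, label=f"EQ{i+1}")
        for i in range(n_equilibrated)
    ]
    return strains


# ---------------------------------------------------------------------------
# Strain-to-model rebuild


def rebuild_strain_model(model, strain: StrainVariant):
    """Rebuild the ME model from a strain's perturbed genome.

    Regenerates the transcription NTP demands, degradation NMP releases and
    translation tRNA stoichiometries from the new sequences while keeping
    the wildtype's reaction/species id sets, bounds and couplings — only
    coefficient values change.
    """
    from .builder import build_me_model_from_config

    rebuilt = build_me_model_from_config(strain.genome, model.config)
    wt_rxns, new_rxns = set(model.reactions), set(rebuilt.reactions)
    if wt_rxns != new_rxns:
        raise ValueError(
            f"strain rebuild changed the reaction set: +{sorted(new_rxns - wt_rxns)[:5]} "
            f"-{sorted(wt_rxns - new_rxns)[:5]}"
        )
    if set(model.species) != set(rebuilt.species):
        raise ValueError("strain rebuild changed the species set")
    # carry over any condition-specific bounds the wildtype model holds
    for rid, rxn in rebuilt.reactions.items():
        rxn.lb = model.reactions[rid].lb
        rxn.ub = model.reactions[rid].ub
    rebuilt.couplings = list(model.couplings)
    return rebuilt


# ---------------------------------------------------------------------------
# Effective codon usage


def effective_codon_usage(
    per_gene_usage: pd.DataFrame, expression_weights: pd.Series
) -> pd.Series:
    """Expression-weighted codon usage: sum_g w_g * usage_g over 61 codons.

    ``per_gene_usage`` has one row per gene and one column per sense codon;
    with all weights 1 this is the plain genome codon usage.
    """
    if len(per_gene_usage) != len(expression_weights):
        raise ValueError(
            f"{len(per_gene_usage)} genes but {len(expression_weights)} weights"
        )
    if (expression_weights < 0).any():
        raise ValueError("expression weights must be non-negative")
    w = expression_weights.reindex(per_gene_usage.index)
    if w.isna().any():
        raise ValueError("weights index does not match gene index")
    return per_gene_usage.mul(w, axis=0).sum(axis=0)


def correlate(u: pd.Series, v: pd.Series) -> float:
    """Pearson correlation between two codon-usage vectors."""
    if len(u) != len(v):
        raise ValueError("usage vectors differ in length")
    return float(np.corrcoef(np.asarray(u, dtype=float), np.asarray(v, dtype=float))[0, 1])
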