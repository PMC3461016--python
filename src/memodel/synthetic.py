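"""Self-contained toy fixtures: genomes with controlled codon bias, a tRNA
recognition map, a small metabolic core with GPRs, media — everything needed
to build and solve an ME model without downloads.

The canonical fixture, "mini-coli", is a ~35-gene organism: a dozen protein
genes encoding the enzymes of a glucose -> energy/precursor -> biomass core
(with isozyme, complex and reversible-reaction cases), 21 tRNA genes
covering the generic recognition map (the six-codon leucine family split
across two species, with CTA read only by the minor tRNA_Leu2), and one
rRNA gene whose transcription cap is deliberately binding so reduced-cost
analyses have a growth-limiting bound to find.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .builder import build_me_model
from .expression import ComplexSpec, Reaction
from .genome import (
    CodonTable,
    Gene,
    Genome,
    TranscriptionUnit,
    TRNARecognitionMap,
    default_trna_map,
    standard_codon_table,
)
from .units import parse_reaction_formula

__all__ = [
    "ToyGenomeSpec",
    "ToyModelSpec",
    "MEFixture",
    "make_toy_genome",
    "make_toy_me_fixture",
    "mini_coli",
    "trna_bottleneck",
    "write_genome_files",
    "extreme_bias_weights",
    "ecoli_like_weights",
]

INF = math.inf
_SPACER = "GCATGCATGC"


@dataclass
class ToyGenomeSpec:
    """Controls for the random protein-gene generator.

    Codon preferences are resolved per synonymous family: explicit
    ``codon_weights`` win, otherwise weights are drawn once per genome from
    a symmetric Dirichlet with the given concentration, otherwise uniform.
    Gene body lengths are in codons (start/stop added on top).
    """

    n_genes: int = 12
    min_len_codons: int = 25
    max_len_codons: int = 40
    aa_alphabet: str = "ADEGKLMSTV"
    codon_weights: dict[str, dict[str, float]] | None = None
    dirichlet_concentration: float | None = None
    tu_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len_codons < 2 or self.max_len_codons < self.min_len_codons:
            raise ValueError("gene body must be at least 2 codons")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")


def extreme_bias_weights(ct: CodonTable | None = None) -> dict[str, dict[str, float]]:
    """One codon per family (the lexicographically first): zero-entropy genomes."""
    ct = ct or standard_codon_table()
    return {aa: {codons[0]: 1.0} for aa, codons in ct.families().items()}


def ecoli_like_weights(ct: CodonTable | None = None) -> dict[str, dict[str, float]]:
    """Uniform within each family except the rare leucine codon CTA (weight 0).

    Mirrors the wildtype situation in which the minor tRNA's codon is barely
    used, so capping its supply leaves the wildtype untouched while a
    recoded strain starves.
    """
    ct = ct or standard_codon_table()
    out = {}
    for aa, codons in ct.families().items():
        w = {c: 1.0 for c in codons}
        if "CTA" in w and len(w) > 1:
            w["CTA"] = 0.0
        out[aa] = w
    return out


def _family_samplers(spec: ToyGenomeSpec, ct: CodonTable, rng: np.random.Generator):
    inv = {aa: codons for aa, codons in ct.families().items()}
    samplers = {}
    for aa, codons in inv.items():
        if spec.codon_weights is not None:
            w = np.array([spec.codon_weights.get(aa, {}).get(c, 0.0) for c in codons])
            if w.sum() == 0:
                w = np.ones(len(codons))
        elif spec.dirichlet_concentration is not None:
            w = rng.dirichlet([spec.dirichlet_concentration] * len(codons))
        else:
            w = np.ones(len(codons))
        samplers[aa] = (codons, w / w.sum())
    return samplers


@dataclass
class _GeneDesign:
    locus_id: str
    name: str
    product_type: str
    tu_id: str
    strand: str
    cds: str  # coding-strand sequence


def _assemble_genome(designs: list[_GeneDesign], codon_table: CodonTable) -> Genome:
    """Lay genes on one chromosome with spacers, strand-aware."""
    from .genome import reverse_complement

    seq_parts = [_SPACER]
    genes: dict[str, Gene] = {}
    tu_members: dict[str, list[str]] = {}
    tu_stable: dict[str, bool] = {}
    pos = len(_SPACER)
    for d in designs:
        start = pos + 1
        end = pos + len(d.cds)
        placed = d.cds if d.strand == "+" else reverse_complement(d.cds)
        seq_parts.append(placed)
        seq_parts.append(_SPACER)
        pos = end + len(_SPACER)
        genes[d.locus_id] = Gene(
            d.locus_id, d.name, start, end, d.strand, d.product_type, d.tu_id
        )
        tu_members.setdefault(d.tu_id, []).append(d.locus_id)
        tu_stable.setdefault(d.tu_id, True)
        tu_stable[d.tu_id] &= d.product_type in ("tRNA", "rRNA")
    tus = {
        tu_id: TranscriptionUnit(
            tu_id, tuple(members), "stable" if tu_stable[tu_id] else "mRNA"
        )
        for tu_id, members in tu_members.items()
    }
    genome = Genome("".join(seq_parts), genes, tus, codon_table)
    genome.validate()
    return genome


def make_toy_genome(spec: ToyGenomeSpec | None = None) -> Genome:
    """Random protein-coding toy genome following the codon-preference weights."""
    spec = spec or ToyGenomeSpec()
    ct = standard_codon_table()
    rng = np.random.default_rng(spec.seed)
    samplers = _family_samplers(spec, ct, rng)
    designs = []
    for i in range(spec.n_genes):
        body_len = int(rng.integers(spec.min_len_codons, spec.max_len_codons + 1))
        body = []
        for _ in range(body_len):
            aa = spec.aa_alphabet[rng.integers(len(spec.aa_alphabet))]
            codons, probs = samplers[aa]
            body.append(codons[rng.choice(len(codons), p=probs)])
        cds = "ATG" + "".join(body) + "TAA"
        tu_idx = i // spec.tu_size
        designs.append(
            _GeneDesign(
                locus_id=f"b{i+1:04d}",
                name=f"gene{i+1}",
                product_type="protein",
                tu_id=f"TU{tu_idx+1:03d}",
                strand="-" if tu_idx % 3 == 2 else "+",
                cds=cds,
            )
        )
    return _assemble_genome(designs, ct)


def write_genome_files(genome: Genome, outdir: str | Path) -> tuple[Path, Path]:
    """Emit FASTA + TSV annotation (the read_genome input formats)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fasta"
    lines = [">chromosome toy genome"]
    seq = genome.sequence
    lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
    fasta.write_text("\n".join(lines) + "\n")
    tsv = outdir / "annotation.tsv"
    rows = ["locus_id\tname\tstart\tend\tstrand\tproduct_type\ttu_id"]
    for g in sorted(genome.genes.values(), key=lambda g: g.start):
        rows.append(
            f"{g.locus_id}\t{g.name}\t{g.start}\t{g.end}\t{g.strand}\t{g.product_type}\t{g.tu_id}"
        )
    tsv.write_text("\n".join(rows) + "\n")
    return fasta, tsv


# ---------------------------------------------------------------------------
# The full ME fixture


@dataclass
class ToyModelSpec:
    """Controls for the toy metabolic core.

    ``n_reactions`` counts GPR-carrying metabolic conversions; the fixed
    backbone (uptake, glycolysis-like energy reactions, precursor synthesis)
    provides four, and peripheral reactions with randomized GPR patterns
    (single / OR / AND, per ``gpr_mix``) fill up the rest.  Biomass is
    producible from the exchange set by construction.
    """

    n_reactions: int = 8
    frac_reversible: float = 0.25
    gpr_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    biomass_aa_coeff: float = 0.2
    biomass_gam: float = 20.0
    seed: int = 0


@dataclass
class MEFixture:
    """A complete toy ME input bundle plus the built model."""

    genome: Genome
    trna_map: TRNARecognitionMap
    metabolic_reactions: list[Reaction]
    complexes: list[ComplexSpec]
    options: dict
    model: "object"  # MEModel; untyped to avoid a circular import at runtime
    media: dict[str, dict]


_AA3 = {
    "A": "ala", "R": "arg", "N": "asn", "D": "asp", "C": "cys", "Q": "gln",
    "E": "glu", "G": "gly", "H": "his", "I": "ile", "L": "leu", "K": "lys",
    "M": "met", "F": "phe", "P": "pro", "S": "ser", "T": "thr", "W": "trp",
    "Y": "tyr", "V": "val",
}


def _backbone_reactions(model_spec: ToyModelSpec) -> list[Reaction]:
    f = parse_reaction_formula
    rxns = [
        Reaction("EX_glc_e", {"glc_e": -1.0}, reversible=True, lb=-10.0, ub=INF,
                 subsystem="Exchange reactions"),
        Reaction("EX_co2_e", {"co2_e": -1.0}, lb=0.0, ub=INF, subsystem="Exchange reactions"),
        Reaction("EX_zn2_e", {"zn2_e": -1.0}, reversible=True, lb=-1000.0, ub=INF,
                 subsystem="Exchange reactions"),
        Reaction("EX_pi_e", {"pi_e": -1.0}, reversible=True, lb=-1000.0, ub=INF,
                 subsystem="Exchange reactions"),
        Reaction("EX_h2o_e", {"h2o_e": -1.0}, reversible=True, lb=-1000.0, ub=INF,
                 subsystem="Exchange reactions"),
        Reaction("EX_h_e", {"h_e": -1.0}, reversible=True, lb=-1000.0, ub=INF,
                 subsystem="Exchange reactions"),
        f("GLCt", "glc[e] -> glc[c]", gpr="b0001", subsystem="Metabolism", ub=INF),
        f("GLYC", "glc[c] + 2 adp[c] + 2 pi[c] -> 2 pyr[c] + 2 atp[c] + 2 h2o[c]",
          gpr="b0002 or b0003", subsystem="Metabolism", ub=INF),
        f("RESP", "pyr[c] + 3 adp[c] + 3 pi[c] -> 3 atp[c] + co2[c] + 3 h2o[c]",
          gpr="b0004 and b0005", subsystem="Metabolism", ub=INF),
        f("PRECS", "glc[c] + atp[c] <=> prec[c] + adp[c] + pi[c]",
          gpr="b0006", subsystem="Metabolism", lb=-INF, ub=INF),
        f("ZNt", "zn2[e] -> zn2[c]", subsystem="Metabolism", ub=INF),
        f("PIt", "pi[e] -> pi[c]", subsystem="Metabolism", ub=INF),
        f("H2Ot", "h2o[e] <=> h2o[c]", subsystem="Metabolism", lb=-INF, ub=INF),
        f("Ht", "h[c] -> h[e]", subsystem="Metabolism", ub=INF),
        f("CO2t", "co2[c] -> co2[e]", subsystem="Metabolism", ub=INF),
        f("PPA", "ppi[c] + h2o[c] -> 2 pi[c]", subsystem="Metabolism", ub=INF),
        f("NDK", "gdp[c] + atp[c] -> gtp[c] + adp[c]", subsystem="Metabolism", ub=INF),
        Reaction("ATPM", {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
                 lb=0.0, ub=INF, subsystem="Metabolism"),
    ]
    for aa1, aa3 in sorted(_AA3.items()):
        rxns.append(
            f(f"AASYN_{aa3}", f"prec[c] + atp[c] -> {aa3}[c] + adp[c] + pi[c]",
              subsystem="Metabolism", ub=INF)
        )
    for x in "agcu":
        rxns.append(
            f(f"NMPSYN_{x}", f"prec[c] + atp[c] -> {x}mp[c] + adp[c]",
              subsystem="Metabolism", ub=INF)
        )
        rxns.append(
            f(f"NMPK_{x}", f"{x}mp[c] + 2 atp[c] -> {x}tp[c] + 2 adp[c]",
              subsystem="Metabolism", ub=INF)
        )
    # biomass: amino acids (adjustable), GAM (adjustable) and small NTP terms
    gam = model_spec.biomass_gam
    stoich = {f"{aa3}_c": -model_spec.biomass_aa_coeff for aa3 in sorted(_AA3.values())}
    stoich.update({"gtp_c": -0.05, "ctp_c": -0.05, "utp_c": -0.05})
    stoich["atp_c"] = stoich.get("atp_c", 0.0) - 0.05 - gam
    stoich["h2o_c"] = -gam
    stoich.update({"adp_c": gam, "pi_c": gam, "h_c": gam})
    rxns.append(Reaction("BIOMASS", stoich, lb=0.0, ub=INF, subsystem="Biomass"))
    return rxns


def _peripheral_reactions(model_spec: ToyModelSpec, gene_pool: list[str]) -> list[Reaction]:
    rng = np.random.default_rng(model_spec.seed)
    n_extra = max(0, model_spec.n_reactions - 4)
    mix = np.array(model_spec.gpr_mix, dtype=float)
    mix = mix / mix.sum()
    rxns = []
    k = 0
    for i in range(n_extra):
        pattern = rng.choice(3, p=mix)
        if pattern == 0:
            gpr = gene_pool[k % len(gene_pool)]
            k += 1
        else:
            g1, g2 = gene_pool[k % len(gene_pool)], gene_pool[(k + 1) % len(gene_pool)]
            k += 2
            gpr = f"{g1} or {g2}" if pattern == 1 else f"{g1} and {g2}"
        reversible = bool(rng.random() < model_spec.frac_reversible)
        arrow = "<=>" if reversible else "->"
        rxns.append(
            parse_reaction_formula(
                f"PER{i+1}", f"prec[c] {arrow} per{i+1}[c]", gpr=gpr,
                subsystem="Metabolism", lb=-INF if reversible else 0.0, ub=INF,
            )
        )
        rxns.append(
            Reaction(f"DM_per{i+1}", {f"per{i+1}_c": -1.0}, lb=0.0, ub=INF,
                     subsystem="Demands & Sinks")
        )
    return rxns


def _trna_and_rrna_designs(
    trna_map: TRNARecognitionMap, seed: int
) -> list[_GeneDesign]:
    rng = np.random.default_rng(seed + 7919)
    designs = []
    for j, species in enumerate(trna_map.species):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=72))
        tu = "TU_trna_leu2" if species == "tRNA_Leu2" else "TU_trna_main"
        designs.append(
            _GeneDesign(f"b9{j+1:03d}", species, "tRNA", tu, "+", seq)
        )
    rrna_seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=120))
    designs.append(_GeneDesign("b9900", "rrnA", "rRNA", "TU_rrna", "+", rrna_seq))
    return designs


def make_toy_me_fixture(
    genome_spec: ToyGenomeSpec | None = None,
    model_spec: ToyModelSpec | None = None,
    rrna_cap: float = 2e-6,
    options: dict | None = None,
    retries: int = 3,
) -> MEFixture:
    """Build the "mini-coli" bundle and verify it grows.

    The rRNA transcription cap defaults to a value that is the binding
    constraint at the default glucose supply, so reduced-cost analyses see a
    growth-limiting bound.  If the generated bundle fails to produce
    positive growth (possible for adversarial specs) the genome seed is
    bumped and generation retried a bounded number of times.
    """
    from .simulate import solve_fba

    genome_spec = genome_spec or ToyGenomeSpec(codon_weights=ecoli_like_weights())
    model_spec = model_spec or ToyModelSpec()
    trna_map = default_trna_map()

    last_error = None
    for attempt in range(retries):
        spec = ToyGenomeSpec(**{**genome_spec.__dict__, "seed": genome_spec.seed + attempt})
        protein_genome = make_toy_genome(spec)
        designs = [
            _GeneDesign(
                g.locus_id, g.name, g.product_type, g.tu_id, g.strand,
                protein_genome.gene_sequence(g.locus_id),
            )
            for g in sorted(protein_genome.genes.values(), key=lambda g: g.start)
        ]
        designs += _trna_and_rrna_designs(trna_map, spec.seed)
        genome = _assemble_genome(designs, protein_genome.codon_table)

        gene_pool = [f"b{i+1:04d}" for i in range(6, spec.n_genes)] or ["b0006"]
        reactions = _backbone_reactions(model_spec) + _peripheral_reactions(
            model_spec, gene_pool
        )
        complexes = [
            ComplexSpec("b0004_b0005", (("b0004", 1), ("b0005", 1)), (("zn2_c", None),))
        ]
        opts = {
            "biomass_gam": model_spec.biomass_gam,
            "caps": {"overrides": {"TU_rrna": rrna_cap}},
            **(options or {}),
        }
        model = build_me_model(genome, trna_map, reactions, complexes, opts)
        sol = solve_fba(model)
        if sol.optimal and sol.objective_value > 0:
            media = {
                "glc_minimal": {"EX_glc_e": (-10.0, INF)},
                "glc_low": {"EX_glc_e": (-2.0, INF)},
                "no_carbon": {"EX_glc_e": (0.0, INF)},
            }
            return MEFixture(genome, trna_map, reactions, complexes, opts, model, media)
        last_error = f"attempt {attempt}: status {sol.status}, growth {sol.objective_value}"
    raise RuntimeError(f"could not generate a growing fixture: {last_error}")


def mini_coli(seed: int = 1) -> MEFixture:
    """The canonical CI fixture: ~33 genes, positive growth, binding rRNA cap."""
    return make_toy_me_fixture(
        genome_spec=ToyGenomeSpec(seed=seed, codon_weights=ecoli_like_weights()),
        model_spec=ToyModelSpec(seed=seed),
    )


def trna_bottleneck(fixture: MEFixture, cap: float = 1e-8):
    """Construct the tRNA-supply bottleneck experiment at toy scale.

    Caps the minor leucyl-tRNA's transcription unit, then recodes the whole
    leucine family onto CTA (read only by that species).  Returns
    (wildtype_capped_model, strain_model, capped_reaction_id).  The wildtype
    barely uses CTA, so its growth is untouched; the strain funnels all
    leucine demand through the capped species.
    """
    from .evolution import recode_family, rebuild_strain_model

    ini_id = fixture.model.tu_info["TU_trna_leu2"]["ini_id"]
    wt = fixture.model.copy()
    wt.reactions[ini_id].ub = cap
    strain = recode_family(fixture.genome, "CTA")
    strain_model = rebuild_strain_model(wt, strain)
    return wt, strain_model, ini_id
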