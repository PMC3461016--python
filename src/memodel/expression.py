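"""Sequence-specific macromolecular synthesis reactions.

Every reaction here is generated from a template parameterized by the exact
gene sequence: transcription consumes the transcript's NTP letter counts,
degradation releases the matching NMPs, translation consumes one charged
tRNA per codon chosen by the recognition map plus GTP for elongation.
Identical inputs always yield identical reaction sets.

Identifier conventions (followed throughout the package):

===========================  ==============================================
``tscr_ini<TU>[_stab]``      transcription initiation (one per TU)
``tscr_<TU>``                lumped transcription elongation (one per TU)
``<locus>_mRNA_degr1``       mRNA degradation
``tl_ini_<locus>``           translation initiation
``tl_<locus>``               lumped translation elongation
``<locus>_CONV2``            mRNA pool cycling (temporary accumulation)
``CHRG_<tRNA>``              tRNA aminoacylation
``CPLX_<name>``              protein complex formation
``DM_<species>``             demand (dilution) of a macromolecule
``<enz>_EXPcp / _EXPpe``     enzyme export c->p and p->e
===========================  ==============================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genome import (
    CodonTable,
    Gene,
    Genome,
    TranscriptionUnit,
    TRNARecognitionMap,
    extract_gene_sequence,
    split_codons,
)

__all__ = [
    "Species",
    "Reaction",
    "SynthesisCostParams",
    "ComplexSpec",
    "AA_SPECIES",
    "build_transcription_reactions",
    "build_mrna_degradation",
    "build_translation_reactions",
    "build_trna_charging",
    "build_complex_formation",
    "build_enzyme_transport",
    "declare_species",
]

INF = math.inf

SPECIES_KINDS = (
    "metabolite",
    "mRNA",
    "protein",
    "protein_complex",
    "inactive_enzyme",
    "charged_tRNA",
    "uncharged_tRNA",
    "rRNA",
    "ribosome",
)

#: amino-acid one-letter code -> cytosolic metabolite species id
AA_SPECIES = {
    "A": "ala_c", "R": "arg_c", "N": "asn_c", "D": "asp_c", "C": "cys_c",
    "Q": "gln_c", "E": "glu_c", "G": "gly_c", "H": "his_c", "I": "ile_c",
    "L": "leu_c", "K": "lys_c", "M": "met_c", "F": "phe_c", "P": "pro_c",
    "S": "ser_c", "T": "thr_c", "W": "trp_c", "Y": "tyr_c", "V": "val_c",
}

_NTP = {"A": "atp_c", "T": "utp_c", "G": "gtp_c", "C": "ctp_c"}
_NMP = {"A": "amp_c", "T": "ump_c", "G": "gmp_c", "C": "cmp_c"}


@dataclass(frozen=True)
class Species:
    id: str
    kind: str = "metabolite"
    compartment: str = "c"

    def __post_init__(self) -> None:
        if self.kind not in SPECIES_KINDS:
            raise ValueError(f"unknown species kind {self.kind!r}")
        if self.compartment not in ("c", "p", "e"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass
class Reaction:
    """A network reaction: sparse signed stoichiometry plus flux bounds.

    Substrates carry negative coefficients, products positive ones; zero
    coefficients are never stored.  Flux units are mmol·gDW^-1·h^-1 on the
    metabolic scale.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lb: float = 0.0
    ub: float = INF
    subsystem: str = ""
    gpr: str = ""

    def __post_init__(self) -> None:
        self.stoichiometry = {s: c for s, c in self.stoichiometry.items() if c != 0}
        if not self.reversible and self.lb < 0:
            raise ValueError(f"{self.id}: irreversible reaction with lb < 0")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            self.id, dict(self.stoichiometry), self.reversible,
            self.lb, self.ub, self.subsystem, self.gpr,
        )


@dataclass(frozen=True)
class SynthesisCostParams:
    """Energy stoichiometry knobs for the synthesis templates.

    Defaults: one pyrophosphate released per NTP incorporated, 2 GTP per
    translated codon (binding + translocation), 1 ATP per tRNA charging and
    one NMP released per degraded nucleotide.  All configurable because
    published template sub-step costs vary between reconstructions.
    """

    ppi_per_ntp: float = 1.0
    gtp_per_codon: float = 2.0
    atp_per_charging: float = 1.0
    nmp_per_nt: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ppi_per_ntp", "gtp_per_codon", "atp_per_charging", "nmp_per_nt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def transcript_species_id(gene: Gene) -> str:
    """Species produced when a gene's TU is transcribed."""
    if gene.product_type == "protein":
        return f"mRNA_{gene.locus_id}"
    if gene.product_type == "tRNA":
        return gene.name  # tRNA genes are annotated with their species id
    return f"rRNA_{gene.locus_id}" if gene.product_type == "rRNA" else f"miscRNA_{gene.locus_id}"


def nucleotide_counts(seq: str) -> dict[str, int]:
    return {nt: seq.count(nt) for nt in "ACGT"}


# ---------------------------------------------------------------------------
# Transcription / degradation


def transcription_initiation_id(tu: TranscriptionUnit) -> str:
    return f"tscr_ini{tu.tu_id}" + ("_stab" if tu.rna_class == "stable" else "")


def build_transcription_reactions(
    tu: TranscriptionUnit,
    genome: Genome,
    params: SynthesisCostParams | None = None,
) -> list[Reaction]:
    """Initiation plus one lumped elongation reaction for a transcription unit.

    Elongation consumes the NTP letter counts of the TU transcript (T on the
    coding strand maps to UTP) and releases one PPi per nucleotide;
    polycistronic cleavage is modeled as stoichiometric release of one
    transcript species per member gene.
    """
    params = params or SynthesisCostParams()
    genes = [genome.genes[i] for i in tu.gene_ids]
    if not genes:
        raise ValueError(f"TU {tu.tu_id} is empty")
    if len({g.strand for g in genes}) != 1:
        raise ValueError(f"TU {tu.tu_id} mixes strands")

    txn = f"txn_{tu.tu_id}"
    ini = Reaction(
        transcription_initiation_id(tu),
        {txn: 1.0},
        subsystem="Transcription",
    )
    stoich: dict[str, float] = {txn: -1.0}
    total_nt = 0
    for gene in genes:
        seq = extract_gene_sequence(genome, gene)
        total_nt += len(seq)
        for nt, count in nucleotide_counts(seq).items():
            if count:
                stoich[_NTP[nt]] = stoich.get(_NTP[nt], 0.0) - count
        stoich[transcript_species_id(gene)] = stoich.get(transcript_species_id(gene), 0.0) + 1.0
    stoich["ppi_c"] = params.ppi_per_ntp * total_nt
    elong = Reaction(f"tscr_{tu.tu_id}", stoich, subsystem="Transcription")
    return [ini, elong]


def build_mrna_degradation(
    gene: Gene, genome: Genome, params: SynthesisCostParams | None = None
) -> Reaction:
    """Degrade one mRNA into its exact NMP letter counts."""
    params = params or SynthesisCostParams()
    if gene.product_type != "protein":
        raise ValueError(f"{gene.locus_id}: mRNA degradation applies to protein genes only")
    seq = extract_gene_sequence(genome, gene)
    stoich: dict[str, float] = {f"mRNA_{gene.locus_id}": -1.0}
    for nt, count in nucleotide_counts(seq).items():
        if count:
            stoich[_NMP[nt]] = params.nmp_per_nt * count
    return Reaction(f"{gene.locus_id}_mRNA_degr1", stoich, subsystem="mRNA degradation")


# ---------------------------------------------------------------------------
# Translation


def build_translation_reactions(
    gene: Gene,
    genome: Genome,
    codon_table: CodonTable,
    trna_map: TRNARecognitionMap,
    params: SynthesisCostParams | None = None,
    ribosome_usage: float = 1e-3,
    ribosomes_per_mrna: float = 1.0,
) -> list[Reaction]:
    """Translation initiation, lumped elongation, and mRNA pool cycling.

    One translation event engages ``ribosomes_per_mrna`` ribosomes (the
    default single-ribosome variant; the maximal-density variant raises the
    multiplier), each drawing ``ribosome_usage`` of the ribosome pool — the
    fraction of a ribosome diluted away per translation.  Elongation
    consumes, per codon (start included, stop excluded), one charged tRNA
    selected by the recognition map and ``gtp_per_codon`` GTP, and releases
    the uncharged tRNAs.  The ``_CONV2`` reaction returns used mRNA to the
    pool so transcripts cycle until degraded; the coupling layer bounds how
    many translations each transcript supports.
    """
    params = params or SynthesisCostParams()
    if gene.product_type != "protein":
        raise ValueError(f"{gene.locus_id}: translation applies to protein genes only")
    seq = extract_gene_sequence(genome, gene)
    codons = split_codons(seq)
    if codons[-1] not in codon_table.stop_codons:
        raise ValueError(f"{gene.locus_id}: sequence does not end in a stop codon")
    coding = codons[:-1]

    locus = gene.locus_id
    mrna, bound, used = f"mRNA_{locus}", f"mRNA_{locus}_rib", f"mRNA_{locus}_used"
    ini = Reaction(
        f"tl_ini_{locus}",
        {mrna: -1.0, "ribosome_c": -ribosome_usage * ribosomes_per_mrna, bound: 1.0},
        subsystem="Translation",
    )

    stoich: dict[str, float] = {bound: -1.0}
    for pos, codon in enumerate(coding):
        if pos > 0 and codon in codon_table.stop_codons:
            raise ValueError(f"{locus}: internal stop codon {codon} at codon {pos}")
        try:
            trna = trna_map.species_for(codon)
        except KeyError:
            raise ValueError(
                f"{locus}: codon {codon} at position {pos} is not readable under the tRNA map"
            ) from None
        stoich[f"{trna}_charged"] = stoich.get(f"{trna}_charged", 0.0) - 1.0
        stoich[trna] = stoich.get(trna, 0.0) + 1.0
    n = len(coding)
    gtp = params.gtp_per_codon * n
    if gtp:
        stoich["gtp_c"] = stoich.get("gtp_c", 0.0) - gtp
        stoich["gdp_c"] = gtp
        stoich["pi_c"] = stoich.get("pi_c", 0.0) + gtp
    stoich[f"protein_{locus}"] = 1.0
    stoich[used] = 1.0
    elong = Reaction(f"tl_{locus}", stoich, subsystem="Translation")

    conv = Reaction(f"{locus}_CONV2", {used: -1.0, mrna: 1.0}, subsystem="Translation")
    return [ini, elong, conv]


def build_trna_charging(
    amino_acid: str,
    trna_species: str,
    params: SynthesisCostParams | None = None,
) -> Reaction:
    """Aminoacylation: uncharged tRNA + amino acid + ATP -> charged tRNA + AMP + PPi."""
    params = params or SynthesisCostParams()
    if amino_acid not in AA_SPECIES:
        raise ValueError(f"unknown amino acid {amino_acid!r}")
    stoich = {
        trna_species: -1.0,
        AA_SPECIES[amino_acid]: -1.0,
        f"{trna_species}_charged": 1.0,
    }
    if params.atp_per_charging:
        stoich["atp_c"] = -params.atp_per_charging
        stoich["amp_c"] = params.atp_per_charging
        stoich["ppi_c"] = params.atp_per_charging
    return Reaction(f"CHRG_{trna_species}", stoich, subsystem="tRNA charging")


# ---------------------------------------------------------------------------
# Complex formation and enzyme transport


@dataclass(frozen=True)
class ComplexSpec:
    """Subunit composition of a protein complex.

    ``ions`` maps an ion/prosthetic-group species to a count; a count of
    ``None`` means the stoichiometry is unknown and defaults to one ion per
    monomer (summed over subunit copies).
    """

    complex_id: str
    subunits: tuple[tuple[str, int], ...]  # (locus_id, copies)
    ions: tuple[tuple[str, int | None], ...] = ()

    @property
    def n_monomers(self) -> int:
        return sum(copies for _, copies in self.subunits)


def build_complex_formation(spec: ComplexSpec) -> Reaction:
    """All subunits (and any ions) bind simultaneously in one composite reaction."""
    if not spec.subunits:
        raise ValueError(f"{spec.complex_id}: empty subunit list")
    stoich: dict[str, float] = {}
    for locus, copies in spec.subunits:
        stoich[f"protein_{locus}"] = stoich.get(f"protein_{locus}", 0.0) - copies
    for ion, count in spec.ions:
        n = spec.n_monomers if count is None else count
        stoich[ion] = stoich.get(ion, 0.0) - n
    stoich[f"cplx_{spec.complex_id}"] = 1.0
    return Reaction(
        f"CPLX_{spec.complex_id}", stoich, subsystem="Protein complex formation"
    )


def build_enzyme_transport(enzyme_species: str, target_compartment: str) -> list[Reaction]:
    """Export an enzyme to the periplasm (one step) or extracellular space (two steps)."""
    if target_compartment == "c":
        return []
    if target_compartment not in ("p", "e"):
        raise ValueError(f"unknown compartment {target_compartment!r}")
    cp = Reaction(
        f"{enzyme_species}_EXPcp",
        {enzyme_species: -1.0, f"{enzyme_species}_p": 1.0},
        subsystem="Enzyme transport",
    )
    if target_compartment == "p":
        return [cp]
    pe = Reaction(
        f"{enzyme_species}_EXPpe",
        {f"{enzyme_species}_p": -1.0, f"{enzyme_species}_e": 1.0},
        subsystem="Enzyme transport",
    )
    return [cp, pe]


# ---------------------------------------------------------------------------
# Species inference


def declare_species(reactions: list[Reaction]) -> dict[str, Species]:
    """Derive Species records for every id referenced by a reaction set.

    Kind and compartment are inferred from the package's deterministic
    naming conventions.
    """
    out: dict[str, Species] = {}
    for rxn in reactions:
        for sid in rxn.stoichiometry:
            if sid not in out:
                out[sid] = _infer_species(sid)
    return dict(sorted(out.items()))


def _infer_species(sid: str) -> Species:
    compartment = "c"
    if sid.endswith("_p"):
        compartment = "p"
    elif sid.endswith("_e"):
        compartment = "e"
    if sid.startswith("mRNA_") or sid.startswith("miscRNA_"):
        kind = "mRNA"
    elif sid.startswith("rRNA_"):
        kind = "rRNA"
    elif sid.startswith("tRNA_"):
        kind = "charged_tRNA" if sid.endswith("_charged") else "uncharged_tRNA"
    elif sid.startswith("protein_"):
        kind = "inactive_enzyme" if ("_act" in sid or "_inact" in sid) else "protein"
    elif sid.startswith("cplx_"):
        kind = "inactive_enzyme" if ("_act" in sid or "_inact" in sid) else "protein_complex"
    elif sid.startswith("ribosome"):
        kind = "ribosome"
    else:
        kind = "metabolite"
    return Species(sid, kind, compartment)
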