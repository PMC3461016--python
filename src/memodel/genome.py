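"""Annotated genomes, genetic code and tRNA-codon recognition.

This module holds the sequence layer of an ME (metabolism and expression)
model: a single-chromosome genome, its genes grouped into transcription
units, the genetic code, and the map saying which tRNA species reads which
codon.  All synthesis reactions downstream are parameterized by the exact
nucleotide sequences represented here, so validation is strict: coordinates
are 1-based inclusive (GenBank convention), protein-coding genes must be a
whole number of codons, start with a start codon and end with a stop codon,
and ambiguity codes are rejected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq

__all__ = [
    "Gene",
    "TranscriptionUnit",
    "Genome",
    "CodonTable",
    "TRNARecognitionMap",
    "GenomeValidationError",
    "read_genome",
    "read_annotation",
    "extract_gene_sequence",
    "split_codons",
    "codon_usage",
    "gc_content",
    "standard_codon_table",
    "load_trna_map",
    "default_trna_map",
]

PRODUCT_TYPES = ("protein", "tRNA", "rRNA", "miscRNA")
STABLE_TYPES = ("tRNA", "rRNA")

ANNOTATION_COLUMNS = ["locus_id", "name", "start", "end", "strand", "product_type", "tu_id"]


class GenomeValidationError(ValueError):
    """An annotated genome violates a structural invariant."""


@dataclass(frozen=True)
class Gene:
    """One gene: 1-based inclusive coordinates on a single chromosome."""

    locus_id: str
    name: str
    start: int
    end: int
    strand: str
    product_type: str
    tu_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeValidationError(f"{self.locus_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(f"{self.locus_id}: strand must be '+' or '-'")
        if self.product_type not in PRODUCT_TYPES:
            raise GenomeValidationError(
                f"{self.locus_id}: product_type {self.product_type!r} not in {PRODUCT_TYPES}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_protein(self) -> bool:
        return self.product_type == "protein"


@dataclass(frozen=True)
class TranscriptionUnit:
    """A co-transcribed, contiguous gene group (the unit transcription acts on)."""

    tu_id: str
    gene_ids: tuple[str, ...]
    rna_class: str  # "stable" or "mRNA"

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise GenomeValidationError(f"TU {self.tu_id} has no member genes")
        if self.rna_class not in ("stable", "mRNA"):
            raise GenomeValidationError(f"TU {self.tu_id}: rna_class must be 'stable' or 'mRNA'")


@dataclass
class Genome:
    """A validated single-chromosome genome with gene and TU annotation."""

    sequence: str
    genes: dict[str, Gene]
    tus: dict[str, TranscriptionUnit]
    codon_table: "CodonTable" = None  # set in validate() if None

    def __post_init__(self) -> None:
        if self.codon_table is None:
            self.codon_table = standard_codon_table()

    def validate(self) -> None:
        bad = [c for c in set(self.sequence) if c not in "ACGT"]
        if bad:
            raise GenomeValidationError(f"non-ACGT characters in sequence: {sorted(bad)}")
        n = len(self.sequence)
        offenders = [g.locus_id for g in self.genes.values() if g.end > n or g.start < 1]
        if offenders:
            raise GenomeValidationError(f"gene coordinates out of range: {offenders}")
        # overlapping genes are not supported (a gene belongs to one TU slice)
        spans = sorted((g.start, g.end, g.locus_id) for g in self.genes.values())
        overlaps = [
            (a[2], b[2]) for a, b in zip(spans, spans[1:]) if b[0] <= a[1]
        ]
        if overlaps:
            raise GenomeValidationError(f"overlapping gene coordinates: {overlaps}")
        for g in self.genes.values():
            if g.tu_id not in self.tus:
                raise GenomeValidationError(f"{g.locus_id}: unknown TU {g.tu_id}")
            if g.is_protein:
                self._validate_cds(g)
        for tu in self.tus.values():
            members = [self.genes[i] for i in tu.gene_ids if i in self.genes]
            if len(members) != len(tu.gene_ids):
                missing = set(tu.gene_ids) - set(self.genes)
                raise GenomeValidationError(f"TU {tu.tu_id} lists unknown genes: {sorted(missing)}")
            strands = {g.strand for g in members}
            if len(strands) != 1:
                raise GenomeValidationError(f"TU {tu.tu_id} mixes strands")
            all_stable = all(g.product_type in STABLE_TYPES for g in members)
            if (tu.rna_class == "stable") != all_stable:
                raise GenomeValidationError(
                    f"TU {tu.tu_id}: rna_class {tu.rna_class!r} inconsistent with member types"
                )

    def _validate_cds(self, gene: Gene) -> None:
        if gene.length % 3 != 0:
            raise GenomeValidationError(
                f"{gene.locus_id}: protein gene length {gene.length} not divisible by 3"
            )
        seq = extract_gene_sequence(self, gene)
        ct = self.codon_table
        if seq[:3] not in ct.start_codons:
            raise GenomeValidationError(f"{gene.locus_id}: no start codon ({seq[:3]})")
        if seq[-3:] not in ct.stop_codons:
            raise GenomeValidationError(f"{gene.locus_id}: no stop codon ({seq[-3:]})")
        for i, codon in enumerate(split_codons(seq)[:-1]):
            if i > 0 and codon in ct.stop_codons:
                raise GenomeValidationError(
                    f"{gene.locus_id}: internal stop codon {codon} at codon {i}"
                )

    # -- convenience ------------------------------------------------------
    def protein_genes(self) -> list[Gene]:
        return [g for g in self.genes.values() if g.is_protein]

    def gene_sequence(self, locus_id: str) -> str:
        return extract_gene_sequence(self, self.genes[locus_id])

    def with_sequence(self, sequence: str) -> "Genome":
        """A copy of this genome carrying a perturbed chromosome sequence."""
        g = Genome(sequence, dict(self.genes), dict(self.tus), self.codon_table)
        g.validate()
        return g


# ---------------------------------------------------------------------------
# Genetic code and tRNA recognition


@dataclass(frozen=True)
class CodonTable:
    """Genetic code: codon -> amino acid (one-letter), stop and start codons."""

    forward: Mapping[str, str]
    stop_codons: frozenset[str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.forward) != 61:
            raise ValueError(f"expected 61 sense codons, got {len(self.forward)}")
        if set(self.forward) & self.stop_codons:
            raise ValueError("sense and stop codon sets overlap")

    @property
    def sense_codons(self) -> list[str]:
        return sorted(self.forward)

    @property
    def amino_acids(self) -> list[str]:
        return sorted(set(self.forward.values()))

    def synonymous_family(self, codon: str) -> list[str]:
        """All sense codons (sorted) encoding the same amino acid as `codon`."""
        aa = self.forward[codon]
        return sorted(c for c, a in self.forward.items() if a == aa)

    def families(self) -> dict[str, list[str]]:
        fam: dict[str, list[str]] = {}
        for c, a in self.forward.items():
            fam.setdefault(a, []).append(c)
        return {a: sorted(cs) for a, cs in fam.items()}

    def translate(self, seq: str) -> str:
        """Protein sequence of a CDS (stop codon dropped)."""
        out = []
        for codon in split_codons(seq):
            if codon in self.stop_codons:
                break
            out.append(self.forward[codon])
        return "".join(out)


def standard_codon_table() -> CodonTable:
    """The bacterial genetic code (NCBI translation table 11)."""
    t = _BioCodonTable.unambiguous_dna_by_id[11]
    return CodonTable(
        forward=dict(t.forward_table),
        stop_codons=frozenset(t.stop_codons),
        start_codons=frozenset(t.start_codons),
    )


@dataclass(frozen=True)
class TRNARecognitionMap:
    """tRNA species -> set of codons read.

    Generic species may stand for several isoacceptors; a species may read
    multiple codons, and translation picks one species per codon
    deterministically (lexicographically smallest reading species).
    """

    reads: Mapping[str, frozenset[str]]

    def validate(self, codon_table: CodonTable) -> None:
        covered = set().union(*self.reads.values()) if self.reads else set()
        missing = set(codon_table.forward) - covered
        if missing:
            raise ValueError(f"sense codons not read by any tRNA species: {sorted(missing)}")

    def species_for(self, codon: str) -> str:
        hits = sorted(s for s, codons in self.reads.items() if codon in codons)
        if not hits:
            raise KeyError(f"no tRNA species reads codon {codon}")
        return hits[0]

    @property
    def species(self) -> list[str]:
        return sorted(self.reads)


def load_trna_map(path: str | Path) -> TRNARecognitionMap:
    """Read a tRNA recognition map from YAML ({species: [codons]})."""
    raw = yaml.safe_load(Path(path).read_text())
    return TRNARecognitionMap({s: frozenset(c) for s, c in raw.items()})


def default_trna_map() -> TRNARecognitionMap:
    """Generic one-species-per-amino-acid map, with leucine split in two.

    Each synonymous family is read by one generic species standing for all
    isoacceptors, except the six-codon leucine family which is split between
    a major species (tRNA_Leu1) and a single-codon minor species (tRNA_Leu2,
    reading CTA only) so tRNA-supply bottlenecks can be exercised.
    """
    ct = standard_codon_table()
    aa_names = {
        "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
        "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
        "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
        "Y": "Tyr", "V": "Val",
    }
    reads: dict[str, frozenset[str]] = {}
    for aa, codons in ct.families().items():
        name = aa_names[aa]
        if aa == "L":
            reads["tRNA_Leu1"] = frozenset(c for c in codons if c != "CTA")
            reads["tRNA_Leu2"] = frozenset({"CTA"})
        else:
            reads[f"tRNA_{name}"] = frozenset(codons)
    m = TRNARecognitionMap(reads)
    m.validate(ct)
    return m


# ---------------------------------------------------------------------------
# Sequence operations

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_gene_sequence(genome: Genome, gene: Gene) -> str:
    """Coding-strand sequence of a gene (reverse complement on the − strand)."""
    s = genome.sequence[gene.start - 1 : gene.end]
    return s if gene.strand == "+" else str(Seq(s).reverse_complement())


def split_codons(seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def codon_usage(
    sequences: Iterable[str], codon_table: CodonTable | None = None
) -> pd.Series:
    """Codon counts over the 61 sense codons for a set of coding sequences.

    The start codon is counted as its literal codon; stop codons are
    excluded.  Every sequence must end in a stop codon.
    """
    ct = codon_table or standard_codon_table()
    counts: Counter[str] = Counter()
    for seq in sequences:
        codons = split_codons(seq)
        if codons[-1] not in ct.stop_codons:
            raise ValueError(f"coding sequence does not end in a stop codon: ...{codons[-1]}")
        for codon in codons[:-1]:
            if codon not in ct.forward:
                raise ValueError(f"stop codon {codon} inside coding sequence")
            counts[codon] += 1
    return pd.Series(
        [counts.get(c, 0) for c in ct.sense_codons], index=ct.sense_codons, dtype=int
    )


def gc_content(sequences: Iterable[str]) -> float:
    """(#G + #C) / total nucleotides over a non-empty set of sequences."""
    total = 0
    gc = 0
    for seq in sequences:
        total += len(seq)
        gc += seq.count("G") + seq.count("C")
    if total == 0:
        raise ValueError("gc_content of an empty gene set is undefined")
    return gc / total


# ---------------------------------------------------------------------------
# Readers


def read_annotation(path: str | Path, dialect: str = "tsv") -> tuple[dict[str, Gene], dict[str, TranscriptionUnit]]:
    """Read gene/TU annotation from TSV (fixed header) or the GFF3 dialect."""
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "tu_id": str})
        missing = set(ANNOTATION_COLUMNS) - set(df.columns)
        if missing:
            raise GenomeValidationError(f"annotation missing columns: {sorted(missing)}")
        records = df.to_dict("records")
    elif dialect == "gff3":
        records = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    genes: dict[str, Gene] = {}
    tu_members: dict[str, list[tuple[int, str]]] = {}
    tu_types: dict[str, list[str]] = {}
    for r in records:
        g = Gene(
            locus_id=str(r["locus_id"]),
            name=str(r["name"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=str(r["strand"]),
            product_type=str(r["product_type"]),
            tu_id=str(r["tu_id"]),
        )
        if g.locus_id in genes:
            raise GenomeValidationError(f"duplicate locus_id {g.locus_id}")
        genes[g.locus_id] = g
        tu_members.setdefault(g.tu_id, []).append((g.start, g.locus_id))
        tu_types.setdefault(g.tu_id, []).append(g.product_type)

    tus = {}
    for tu_id, members in tu_members.items():
        ordered = tuple(locus for _, locus in sorted(members))
        stable = all(t in STABLE_TYPES for t in tu_types[tu_id])
        tus[tu_id] = TranscriptionUnit(tu_id, ordered, "stable" if stable else "mRNA")
    return genes, tus


def _read_gff3(path: str | Path) -> list[dict]:
    """Minimal GFF3 dialect: gene features with ID/Name/product_type/tu_id attributes."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9 or cols[2] != "gene":
            continue
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        records.append(
            {
                "locus_id": attrs["ID"],
                "name": attrs.get("Name", attrs["ID"]),
                "start": int(cols[3]),
                "end": int(cols[4]),
                "strand": cols[6],
                "product_type": attrs.get("product_type", "protein"),
                "tu_id": attrs["tu_id"],
            }
        )
    return records


def read_genome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    dialect: str = "tsv",
    codon_table: CodonTable | None = None,
) -> Genome:
    """Read and validate a genome from FASTA + tabular annotation."""
    recs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(recs) != 1:
        raise GenomeValidationError(f"expected one chromosome record, found {len(recs)}")
    sequence = str(recs[0].seq).upper()
    genes, tus = read_annotation(annotation_path, dialect=dialect)
    genome = Genome(sequence, genes, tus, codon_table or standard_codon_table())
    genome.validate()
    return genome
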