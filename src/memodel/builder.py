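"""End-to-end construction of an ME model from an annotated genome, a tRNA
recognition map and a GPR-annotated metabolic reaction list.

The builder (i) expands the metabolic reactions into enzyme-explicit
metabolic units, (ii) generates all sequence-specific expression reactions,
(iii) merges both parts into one model, and (iv) attaches the three coupling
families: mRNA->translation (per protein gene, with half-life-derived
coefficients), enzyme demand->catalytic recycle (per metabolic unit) and
tRNA transcription->charging (per tRNA species).  The full input set is
stored on ``model.config`` in serialized form so a strain rebuild can
regenerate the model from a perturbed genome with identical structure.
"""

from __future__ import annotations

import math

from .expression import (
    AA_SPECIES,
    ComplexSpec,
    Reaction,
    SynthesisCostParams,
    build_mrna_degradation,
    build_transcription_reactions,
    build_translation_reactions,
    build_trna_charging,
    declare_species,
    transcription_initiation_id,
)
from .genome import Genome, TRNARecognitionMap, extract_gene_sequence, split_codons
from .model import (
    MEModel,
    ModelPart,
    TranslationCouplingParams,
    add_coupling,
    assemble,
    mrna_coupling_coefficient,
    set_transcription_caps,
    BiomassTags,
)
from .units import expand_reactions, strip_trna_charging

__all__ = ["DEFAULT_OPTIONS", "build_me_model", "build_me_model_from_config"]

INF = math.inf

#: JSON-safe builder options; see docs/methods.md for the rationale of each.
DEFAULT_OPTIONS: dict = {
    "costs": {"ppi_per_ntp": 1.0, "gtp_per_codon": 2.0, "atp_per_charging": 1.0, "nmp_per_nt": 1.0},
    "ribosome_usage": 1e-3,       # ribosome pool fraction consumed per translation
    "ribosomes_per_mrna": 1.0,    # single-ribosome variant; raise for max density
    "translation_rate_aa_s": 12.0,
    "t_half_min": 0.1,
    "t_half_max": 60.0,
    "enzyme_coupling": {"c_min": 1.0, "c_max": 10000.0},
    "trna_coupling": {"c_min": 0.0, "c_max": 1000.0},
    "caps": {
        "doubling_time_min": 24.0,
        "stable_rate_nt_s": 85.0,
        "mrna_rate_nt_s": 55.0,
        "overrides": {},
    },
    "biomass_id": "BIOMASS",
    "biomass_aa_species": sorted(AA_SPECIES.values()),
    "biomass_gam": 20.0,
    "atpm_id": "ATPM",
    "atpm_lb": 0.0,
}


def _merged_options(options: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_OPTIONS.items()}
    for k, v in (options or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _serialize_reaction(r: Reaction) -> dict:
    def _num(x):
        return "inf" if x == INF else ("-inf" if x == -INF else x)

    return {
        "id": r.id,
        "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
        "reversible": r.reversible,
        "lb": _num(r.lb),
        "ub": _num(r.ub),
        "subsystem": r.subsystem,
        "gpr": r.gpr,
    }


def _deserialize_reaction(d: dict) -> Reaction:
    def _num(x):
        return INF if x == "inf" else (-INF if x == "-inf" else float(x))

    return Reaction(
        d["id"], dict(d["stoichiometry"]), d["reversible"],
        _num(d["lb"]), _num(d["ub"]), d["subsystem"], d["gpr"],
    )


def build_me_model(
    genome: Genome,
    trna_map: TRNARecognitionMap,
    metabolic_reactions: list[Reaction],
    complexes: list[ComplexSpec] = (),
    options: dict | None = None,
) -> MEModel:
    """Assemble a coupled metabolism-and-expression model.

    ``metabolic_reactions`` must include the exchange reactions, the biomass
    reaction (id ``options['biomass_id']``) and any maintenance reaction;
    metabolic-side tRNA-charging duplicates are stripped before integration.
    """
    opts = _merged_options(options)
    genome.validate()
    ct = genome.codon_table
    trna_map.validate(ct)
    costs = SynthesisCostParams(**opts["costs"])

    # -- metabolic part: enzyme-explicit expansion --------------------------
    metabolic = strip_trna_charging(metabolic_reactions)
    cplx_index = {tuple(sorted(l for l, _ in spec.subunits)): spec for spec in complexes}
    expansion = expand_reactions(metabolic, complexes=cplx_index)

    # -- expression part ----------------------------------------------------
    expr: list[Reaction] = []
    tu_info: dict[str, dict] = {}
    for tu_id in sorted(genome.tus):
        tu = genome.tus[tu_id]
        rxns = build_transcription_reactions(tu, genome, costs)
        expr.extend(rxns)
        length = sum(genome.genes[g].length for g in tu.gene_ids)
        tu_info[tu_id] = {
            "ini_id": transcription_initiation_id(tu),
            "length": length,
            "stable": tu.rna_class == "stable",
            "dosage": 1.0,
        }

    gene_expr: dict[str, list[str]] = {}
    protein_lengths: dict[str, int] = {}
    for gene in sorted(genome.protein_genes(), key=lambda g: g.locus_id):
        degr = build_mrna_degradation(gene, genome, costs)
        tl = build_translation_reactions(
            gene, genome, ct, trna_map, costs,
            ribosome_usage=opts["ribosome_usage"],
            ribosomes_per_mrna=opts["ribosomes_per_mrna"],
        )
        expr.append(degr)
        expr.extend(tl)
        gene_expr[gene.locus_id] = [degr.id] + [r.id for r in tl]
        protein_lengths[gene.locus_id] = gene.length // 3 - 1  # aa, stop excluded

    # tRNA species with a source gene: charging + dilution demand
    trna_source_tu: dict[str, str] = {}
    for gene in genome.genes.values():
        if gene.product_type == "tRNA":
            trna_source_tu.setdefault(gene.name, gene.tu_id)
    used_codons = {
        c
        for g in genome.protein_genes()
        for c in split_codons(extract_gene_sequence(genome, g))[:-1]
    }
    for codon in sorted(used_codons):
        if trna_map.species_for(codon) not in trna_source_tu:
            raise ValueError(
                f"codon {codon} is read by {trna_map.species_for(codon)}, "
                "which no gene in the genome produces"
            )
    aa_of_species: dict[str, str] = {}
    for species in sorted(trna_source_tu):
        aas = {ct.forward[c] for c in trna_map.reads[species]}
        if len(aas) != 1:
            raise ValueError(f"{species} reads codons of multiple amino acids: {sorted(aas)}")
        aa_of_species[species] = next(iter(aas))
        expr.append(build_trna_charging(aa_of_species[species], species, costs))
        expr.append(
            Reaction(f"DM_{species}", {species: -1.0}, subsystem="Demands & Sinks")
        )

    # ribosome: single-step assembly from the rRNA species, plus a free sink
    rrna_species = sorted(
        f"rRNA_{g.locus_id}" for g in genome.genes.values() if g.product_type == "rRNA"
    )
    if not rrna_species:
        raise ValueError("genome contains no rRNA gene; ribosome cannot be assembled")
    expr.append(
        Reaction(
            "RIB_ASM",
            {**{s: -1.0 for s in rrna_species}, "ribosome_c": 1.0},
            subsystem="Ribosomal assembly",
        )
    )
    expr.append(Reaction("DM_rib", {"ribosome_c": -1.0}, subsystem="Demands & Sinks"))
    for g in genome.genes.values():
        if g.product_type == "miscRNA":
            expr.append(
                Reaction(f"DM_miscRNA_{g.locus_id}", {f"miscRNA_{g.locus_id}": -1.0},
                         subsystem="Demands & Sinks")
            )

    # -- merge (metabolic-side exchange bounds win) --------------------------
    model = assemble(
        [
            ModelPart("metabolic", expansion.reactions),
            ModelPart("expression", expr),
        ],
        objective_id=opts["biomass_id"],
    )
    model.units = expansion.units
    model.biomass_tags = BiomassTags(
        tuple(opts["biomass_aa_species"]), float(opts["biomass_gam"])
    )
    if opts["atpm_id"] in model.reactions:
        model.reactions[opts["atpm_id"]].lb = float(opts["atpm_lb"])

    # -- couplings -----------------------------------------------------------
    for locus, rxn_ids in sorted(gene_expr.items()):
        params = TranslationCouplingParams(
            rate_aa_per_s=opts["translation_rate_aa_s"],
            length_aa=protein_lengths[locus],
            t_half_min=opts["t_half_min"],
            t_half_max=opts["t_half_max"],
        )
        c_min, c_max = mrna_coupling_coefficient(params)
        add_coupling(
            model, f"{locus}_mRNA_degr1", f"tl_ini_{locus}", c_min, c_max,
            name=f"mrna_{locus}",
        )
    ec = opts["enzyme_coupling"]
    for unit in model.units:
        for rec in unit.recycle_ids:
            add_coupling(
                model, unit.demand_id, rec, ec["c_min"], ec["c_max"],
                name=f"enzyme_{rec}",
            )
    tc = opts["trna_coupling"]
    for species, tu_id in sorted(trna_source_tu.items()):
        add_coupling(
            model, tu_info[tu_id]["ini_id"], f"CHRG_{species}",
            tc["c_min"], tc["c_max"], name=f"trna_{species}",
        )

    # -- caps and bookkeeping -------------------------------------------------
    model.tu_info = tu_info
    caps = opts["caps"]
    set_transcription_caps(
        model,
        doubling_time_min=caps["doubling_time_min"],
        stable_rate_nt_s=caps["stable_rate_nt_s"],
        mrna_rate_nt_s=caps["mrna_rate_nt_s"],
        overrides=caps.get("overrides", {}),
    )

    unit_rxns_by_locus: dict[str, set[str]] = {}
    for unit in model.units:
        for locus in unit.module:
            bag = unit_rxns_by_locus.setdefault(locus, set())
            bag.update(unit.reaction_ids)
            if unit.enzyme_id.startswith("cplx_"):
                cplx_rxn = f"CPLX_{unit.enzyme_id[len('cplx_'):]}"
                if cplx_rxn in model.reactions:
                    bag.add(cplx_rxn)
    gene_index: dict[str, dict] = {}
    for gene in genome.genes.values():
        gene_index[gene.locus_id] = {
            "product_type": gene.product_type,
            "tl_ini": f"tl_ini_{gene.locus_id}" if gene.is_protein else "",
            "expression_reactions": gene_expr.get(gene.locus_id, []),
            "unit_reactions": sorted(unit_rxns_by_locus.get(gene.locus_id, ())),
        }
    model.gene_index = gene_index

    model.config = {
        "trna_map": {s: sorted(c) for s, c in trna_map.reads.items()},
        "metabolic_reactions": [_serialize_reaction(r) for r in metabolic_reactions],
        "complexes": [
            {
                "complex_id": s.complex_id,
                "subunits": [list(t) for t in s.subunits],
                "ions": [list(t) for t in s.ions],
            }
            for s in complexes
        ],
        "options": opts,
    }
    return model


def build_me_model_from_config(genome: Genome, config: dict) -> MEModel:
    """Rebuild a model from a (possibly perturbed) genome and a stored config."""
    trna_map = TRNARecognitionMap(
        {s: frozenset(c) for s, c in config["trna_map"].items()}
    )
    reactions = [_deserialize_reaction(d) for d in config["metabolic_reactions"]]
    complexes = [
        ComplexSpec(
            d["complex_id"],
            tuple((l, int(n)) for l, n in d["subunits"]),
            tuple((ion, None if n is None else int(n)) for ion, n in d["ions"]),
        )
        for d in config["complexes"]
    ]
    return build_me_model(genome, trna_map, reactions, complexes, config["options"])
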