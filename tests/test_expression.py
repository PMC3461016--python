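"""Sequence-parameterized synthesis reaction templates."""

import pytest

from memodel.expression import (
    ComplexSpec,
    Reaction,
    SynthesisCostParams,
    build_complex_formation,
    build_enzyme_transport,
    build_mrna_degradation,
    build_transcription_reactions,
    build_translation_reactions,
    build_trna_charging,
)
from memodel.genome import Gene, Genome, TranscriptionUnit, standard_codon_table
from memodel.synthetic import ToyGenomeSpec, make_toy_genome


def _genome_of(*cds, product_type="protein"):
    """One TU holding the given coding sequences laid end to end."""
    pos = 1
    genes = {}
    seq = ""
    for i, s in enumerate(cds):
        locus = f"b{i+1}"
        genes[locus] = Gene(locus, locus, pos, pos + len(s) - 1, "+", product_type, "TU1")
        seq += s
        pos += len(s)
    tus = {"TU1": TranscriptionUnit("TU1", tuple(genes), "mRNA" if product_type == "protein" else "stable")}
    return Genome(seq, genes, tus)


class TestTranscription:
    def test_letter_counts_of_single_gene_tu(self):
        genome = _genome_of("ATGAAATAG")
        ini, elong = build_transcription_reactions(genome.tus["TU1"], genome)
        assert ini.id == "tscr_iniTU1"
        s = elong.stoichiometry
        assert s["atp_c"] == -5 and s["utp_c"] == -2 and s["gtp_c"] == -2
        assert "ctp_c" not in s
        assert s["ppi_c"] == 9 and s["mRNA_b1"] == 1

    def test_two_gene_tu_sums_counts_and_releases_two_mrnas(self):
        genome = _genome_of("ATGAAATAG", "ATGCCCTAA")
        _, elong = build_transcription_reactions(genome.tus["TU1"], genome)
        s = elong.stoichiometry
        # brute-force letter counting over the concatenated transcript
        concat = "ATGAAATAGATGCCCTAA"
        assert s["atp_c"] == -concat.count("A")
        assert s["utp_c"] == -concat.count("T")
        assert s["gtp_c"] == -concat.count("G")
        assert s["ctp_c"] == -concat.count("C")
        assert s["mRNA_b1"] == 1 and s["mRNA_b2"] == 1
        assert s["ppi_c"] == len(concat)

    def test_stable_tu_gets_stab_suffix(self):
        genome = _genome_of("ACGTACGT", product_type="tRNA")
        ini, _ = build_transcription_reactions(genome.tus["TU1"], genome)
        assert ini.id.endswith("_stab")

    def test_empty_tu_is_an_error(self):
        genome = _genome_of("ATGAAATAG")
        empty = TranscriptionUnit("TU9", ("b1",), "mRNA")
        object.__setattr__(empty, "gene_ids", ())
        with pytest.raises(ValueError):
            build_transcription_reactions(empty, genome)


class TestDegradation:
    def test_nmp_release_mirrors_sequence(self):
        genome = _genome_of("ATGAAATAG")
        r = build_mrna_degradation(genome.genes["b1"], genome)
        assert r.id == "b1_mRNA_degr1"
        assert r.stoichiometry == {"mRNA_b1": -1, "amp_c": 5, "ump_c": 2, "gmp_c": 2}

    def test_nucleotide_conservation_with_transcription(self):
        """Transcription NTP demand equals degradation NMP release, per gene."""
        genome = make_toy_genome(ToyGenomeSpec(n_genes=6, seed=5, tu_size=1))
        pairs = {"atp_c": "amp_c", "utp_c": "ump_c", "gtp_c": "gmp_c", "ctp_c": "cmp_c"}
        for tu in genome.tus.values():
            (gene_id,) = tu.gene_ids
            _, elong = build_transcription_reactions(tu, genome)
            degr = build_mrna_degradation(genome.genes[gene_id], genome)
            for ntp, nmp in pairs.items():
                assert -elong.stoichiometry.get(ntp, 0) == degr.stoichiometry.get(nmp, 0)

    def test_rna_gene_rejected(self):
        genome = _genome_of("ACGTACGT", product_type="tRNA")
        with pytest.raises(ValueError):
            build_mrna_degradation(genome.genes["b1"], genome)


class TestTranslation:
    def test_two_codon_gene_costs(self, ct, trna_map):
        genome = _genome_of("ATGAAATAG")
        ini, elong, conv = build_translation_reactions(
            genome.genes["b1"], genome, ct, trna_map
        )
        assert ini.id == "tl_ini_b1" and conv.id == "b1_CONV2"
        s = elong.stoichiometry
        assert s["tRNA_Met_charged"] == -1  # initiator
        assert s["tRNA_Lys_charged"] == -1
        assert s["gtp_c"] == -4  # 2 codons x 2 GTP
        assert s["protein_b1"] == 1
        # uncharged tRNAs returned
        assert s["tRNA_Met"] == 1 and s["tRNA_Lys"] == 1

    def test_synonymous_codons_read_by_same_generic_trna(self, ct, trna_map):
        g1 = _genome_of("ATGAAATAG")
        g2 = _genome_of("ATGAAGTAG")  # AAA -> AAG, both read by tRNA_Lys
        e1 = build_translation_reactions(g1.genes["b1"], g1, ct, trna_map)[1]
        e2 = build_translation_reactions(g2.genes["b1"], g2, ct, trna_map)[1]
        assert e1.stoichiometry == e2.stoichiometry

    def test_internal_stop_is_an_error(self, ct, trna_map):
        genome = _genome_of("ATGTAAAAATAG")
        with pytest.raises(ValueError, match="stop"):
            build_translation_reactions(genome.genes["b1"], genome, ct, trna_map)

    def test_unreadable_codon_names_codon_and_position(self, ct):
        from memodel.genome import TRNARecognitionMap

        partial = TRNARecognitionMap({"tRNA_Met": frozenset({"ATG"})})
        genome = _genome_of("ATGAAATAG")
        with pytest.raises(ValueError, match="AAA.*position 1"):
            build_translation_reactions(genome.genes["b1"], genome, ct, partial)

    def test_trna_cycle_conservation(self, ct, trna_map):
        """One translation event returns exactly the charged tRNAs it drew,
        so running charging at the matching rate closes the cycle with zero
        net tRNA production or consumption."""
        genome = _genome_of("ATGAAACTGGATTAG")
        elong = build_translation_reactions(genome.genes["b1"], genome, ct, trna_map)[1]
        species = {
            s for s in elong.stoichiometry if s.startswith("tRNA_") and not s.endswith("_charged")
        }
        assert species  # the gene does use tRNAs
        for sid in species:
            used = -elong.stoichiometry[f"{sid}_charged"]
            assert elong.stoichiometry[sid] == used
            charge = build_trna_charging(ct.forward[next(iter(trna_map.reads[sid]))], sid)
            # cycle: charging flux `used` + one translation nets zero tRNA
            assert used * charge.stoichiometry[sid] + elong.stoichiometry[sid] == 0
            assert (
                used * charge.stoichiometry[f"{sid}_charged"]
                + elong.stoichiometry[f"{sid}_charged"]
                == 0
            )

    def test_determinism(self, ct, trna_map):
        genome = _genome_of("ATGAAACTGGATTAG")
        a = build_translation_reactions(genome.genes["b1"], genome, ct, trna_map)
        b = build_translation_reactions(genome.genes["b1"], genome, ct, trna_map)
        assert [(r.id, sorted(r.stoichiometry.items())) for r in a] == [
            (r.id, sorted(r.stoichiometry.items())) for r in b
        ]


class TestCharging:
    def test_lysine_charging_consumes_one_atp(self):
        r = build_trna_charging("K", "tRNA_Lys")
        s = r.stoichiometry
        assert s == {
            "tRNA_Lys": -1, "lys_c": -1, "atp_c": -1,
            "tRNA_Lys_charged": 1, "amp_c": 1, "ppi_c": 1,
        }

    def test_zero_atp_variant_drops_energy_terms(self):
        r = build_trna_charging("K", "tRNA_Lys", SynthesisCostParams(atp_per_charging=0))
        assert "atp_c" not in r.stoichiometry and "amp_c" not in r.stoichiometry

    def test_unknown_amino_acid(self):
        with pytest.raises(ValueError, match="amino acid"):
            build_trna_charging("Z", "tRNA_Z")


class TestComplexFormation:
    def test_stated_stoichiometry(self):
        r = build_complex_formation(
            ComplexSpec("A2B2", (("bA", 2), ("bB", 2)))
        )
        assert r.stoichiometry == {"protein_bA": -2, "protein_bB": -2, "cplx_A2B2": 1}

    def test_unknown_ion_count_defaults_to_one_per_monomer(self):
        r = build_complex_formation(
            ComplexSpec("Z", (("bA", 3),), (("zn2_c", None),))
        )
        assert r.stoichiometry["zn2_c"] == -3

    def test_empty_subunits_is_an_error(self):
        with pytest.raises(ValueError):
            build_complex_formation(ComplexSpec("X", ()))


class TestEnzymeTransport:
    @pytest.mark.parametrize("target,n", [("p", 1), ("e", 2), ("c", 0)])
    def test_reaction_counts_by_compartment(self, target, n):
        rxns = build_enzyme_transport("protein_b1", target)
        assert len(rxns) == n

    def test_extracellular_route_goes_via_periplasm(self):
        cp, pe = build_enzyme_transport("protein_b1", "e")
        assert cp.stoichiometry == {"protein_b1": -1, "protein_b1_p": 1}
        assert pe.stoichiometry == {"protein_b1_p": -1, "protein_b1_e": 1}
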