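"""Codon-usage evolution: entropy, strain generators, model rebuilds."""

import math

import numpy as np
import pandas as pd
import pytest

from memodel.evolution import (
    correlate,
    effective_codon_usage,
    generate_biased_strain,
    generate_equilibrated_strain,
    make_strain_library,
    rebuild_strain_model,
    recode_family,
    shannon_entropy,
)
from memodel.genome import codon_usage, split_codons
from memodel.synthetic import ToyGenomeSpec, make_toy_genome

from _oracles import entropy_oracle


def _sequences(genome):
    return {g.locus_id: genome.gene_sequence(g.locus_id) for g in genome.protein_genes()}


class TestShannonEntropy:
    def test_single_codon_amino_acids_have_zero_entropy(self, ct):
        # Met and Trp offer no synonymous choice
        assert shannon_entropy({"g": "ATGTGGATGTGA"}, ct).total == 0.0

    def test_uniform_two_codon_families_give_ln2(self, ct):
        # every amino acid is 2-codon with 50/50 usage: Lys (AAA/AAG) x2, Asn (AAT/AAC) x2
        seq = "ATG" + "AAA" + "AAG" + "AAT" + "AAC" + "TAA"
        h = shannon_entropy({"g": seq}, ct)
        # the start Met contributes 0 with weight 1/5
        assert h.total == pytest.approx((4 / 5) * math.log(2))

    def test_matches_direct_summation_oracle(self, ct):
        genome = make_toy_genome(ToyGenomeSpec(n_genes=50, seed=13, dirichlet_concentration=0.5))
        result = shannon_entropy(_sequences(genome), ct)
        for locus, seq in _sequences(genome).items():
            assert result.per_gene[locus] == pytest.approx(entropy_oracle(seq, ct), abs=1e-12)
        assert result.total == pytest.approx(
            np.mean([entropy_oracle(s, ct) for s in _sequences(genome).values()]), abs=1e-12
        )

    def test_unreadable_codon_is_an_error(self, ct):
        with pytest.raises(ValueError):
            shannon_entropy({"g": "ATGTAATAA"[:3] + "TAA" + "AAA"}, ct)


class TestBiasedStrains:
    def test_forced_swap_removes_all_internal_instances(self, fx, ct):
        strain = generate_biased_strain(fx.genome, seed=0, forced_swaps=[("GAA", "GAG")])
        for locus, seq in _sequences(strain.genome).items():
            internal = split_codons(seq)[1:-1]
            assert "GAA" not in internal, locus
        assert strain.swaps[0][:2] == ("GAA", "GAG")

    def test_protein_sequences_invariant(self, fx, ct):
        strain = generate_biased_strain(fx.genome, m=100, seed=5)
        for locus, seq in _sequences(fx.genome).items():
            assert ct.translate(_sequences(strain.genome)[locus]) == ct.translate(seq)

    def test_start_and_stop_codons_untouched(self, fx):
        strain = generate_biased_strain(fx.genome, m=100, seed=8)
        for locus, seq in _sequences(fx.genome).items():
            new = _sequences(strain.genome)[locus]
            assert new[:3] == seq[:3] and new[-3:] == seq[-3:]

    def test_identical_seed_reproduces_strain(self, fx):
        a = generate_biased_strain(fx.genome, m=50, seed=9)
        b = generate_biased_strain(fx.genome, m=50, seed=9)
        assert a.genome.sequence == b.genome.sequence and a.swaps == b.swaps


class TestEquilibratedStrains:
    def test_hand_executed_single_gene_example(self, ct):
        """ATG AAA AAA TAA with a zeroed counter: first AAA stays (tie ->
        lexicographic AAA), second becomes AAG (counter now favours AAG)."""
        from memodel.genome import Gene, Genome, TranscriptionUnit

        seq = "ATGAAAAAATAA"
        genome = Genome(
            seq,
            {"b1": Gene("b1", "g1", 1, len(seq), "+", "protein", "TU1")},
            {"TU1": TranscriptionUnit("TU1", ("b1",), "mRNA")},
        )
        strain = generate_equilibrated_strain(genome, m=1, seed=0)
        assert strain.genome.gene_sequence("b1") == "ATGAAAAAGTAA"

    def test_family_counts_level_to_within_one(self, fx, ct):
        strain = generate_equilibrated_strain(fx.genome, m=2, seed=4)
        internal = []
        for seq in _sequences(strain.genome).values():
            internal.extend(split_codons(seq)[1:-1])
        counts = pd.Series(internal).value_counts()
        for codons in ct.families().values():
            if len(codons) == 1:
                continue
            family_counts = [int(counts.get(c, 0)) for c in codons]
            assert max(family_counts) - min(family_counts) <= 1

    def test_protein_sequences_invariant(self, fx, ct):
        strain = generate_equilibrated_strain(fx.genome, m=1, seed=2)
        for locus, seq in _sequences(fx.genome).items():
            assert ct.translate(_sequences(strain.genome)[locus]) == ct.translate(seq)


class TestEntropyOrdering:
    def test_biased_below_wildtype_below_equilibrated_over_seeds(self, fx, ct):
        wt = shannon_entropy(_sequences(fx.genome), ct).total
        ok = 0
        seeds = range(10)
        for s in seeds:
            hb = shannon_entropy(
                _sequences(generate_biased_strain(fx.genome, m=100, seed=s).genome), ct
            ).total
            he = shannon_entropy(
                _sequences(generate_equilibrated_strain(fx.genome, m=1, seed=s).genome), ct
            ).total
            ok += he >= wt >= hb
        assert ok >= 9  # the ordering is statistical, not pointwise


class TestStrainModelRebuild:
    def test_identity_strain_rebuilds_bit_identical_model(self, fx):
        identity = generate_biased_strain(fx.genome, seed=0, forced_swaps=[])
        rebuilt = rebuild_strain_model(fx.model, identity)
        assert rebuilt.to_json() == fx.model.to_json()

    def test_reaction_and_species_id_sets_preserved(self, fx):
        strain = generate_biased_strain(fx.genome, m=100, seed=21)
        rebuilt = rebuild_strain_model(fx.model, strain)
        assert set(rebuilt.reactions) == set(fx.model.reactions)
        assert set(rebuilt.species) == set(fx.model.species)

    def test_transcription_ntp_vector_matches_recount(self, fx):
        strain = generate_biased_strain(fx.genome, m=100, seed=22)
        rebuilt = rebuild_strain_model(fx.model, strain)
        ntp = {"atp_c": "A", "ctp_c": "C", "gtp_c": "G", "utp_c": "T"}
        # recount letters directly over each protein TU's transcript
        tu = next(t for t in strain.genome.tus.values() if t.rna_class == "mRNA")
        seq = "".join(strain.genome.gene_sequence(l) for l in tu.gene_ids)
        elong = rebuilt.reactions[f"tscr_{tu.tu_id}"]
        for sp, letter in ntp.items():
            assert -elong.stoichiometry.get(sp, 0) == seq.count(letter)

    def test_recode_family_funnels_usage_onto_target(self, fx, ct):
        strain = recode_family(fx.genome, "CTA")
        usage = codon_usage(_sequences(strain.genome).values(), ct)
        for codon in ct.synonymous_family("CTA"):
            if codon != "CTA":
                assert usage[codon] == 0


class TestEffectiveUsage:
    def _usage_frame(self, fx, ct):
        return pd.DataFrame(
            {l: codon_usage([s], ct) for l, s in _sequences(fx.genome).items()}
        ).T

    def test_unit_weights_recover_plain_usage(self, fx, ct):
        df = self._usage_frame(fx, ct)
        w = pd.Series(1.0, index=df.index)
        total = codon_usage(_sequences(fx.genome).values(), ct)
        assert effective_codon_usage(df, w).equals(total.astype(float))

    def test_single_nonzero_weight_scales_that_gene(self, fx, ct):
        df = self._usage_frame(fx, ct)
        w = pd.Series(0.0, index=df.index)
        w.iloc[0] = 2.5
        eff = effective_codon_usage(df, w)
        assert np.allclose(eff.to_numpy(), 2.5 * df.iloc[0].to_numpy())

    def test_self_correlation_is_one_and_length_mismatch_raises(self, fx, ct):
        df = self._usage_frame(fx, ct)
        u = effective_codon_usage(df, pd.Series(1.0, index=df.index))
        assert correlate(u, u) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            correlate(u, u.iloc[:-1])

    def test_strain_library_preset_sizes(self, fx):
        lib = make_strain_library(fx.genome, n_biased=3, n_equilibrated=2, m=10)
        assert [s.algorithm for s in lib] == ["biased"] * 3 + ["equilibrated"] * 2
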