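# Generic tRNA-codon recognition map: species -> codons read.
# One generic species per amino acid (standing for all isoacceptors),
# with the six-codon leucine family split between tRNA_Leu1 (major)
# and tRNA_Leu2 (reads CTA only).  Editable; a species may read
# multiple codons and every sense codon must be read by >=1 species.
tRNA_Ala: [GCA, GCC, GCG, GCT]
tRNA_Arg: [AGA, AGG, CGA, CGC, CGG, CGT]
tRNA_Asn: [AAC, AAT]
tRNA_Asp: [GAC, GAT]
tRNA_Cys: [TGC, TGT]
tRNA_Gln: [CAA, CAG]
tRNA_Glu: [GAA, GAG]
tRNA_Gly: [GGA, GGC, GGG, GGT]
tRNA_His: [CAC, CAT]
tRNA_Ile: [ATA, ATC, ATT]
tRNA_Leu1: [CTC, CTG, CTT, TTA, TTG]
tRNA_Leu2: [CTA]
tRNA_Lys: [AAA, AAG]
tRNA_Met: [ATG]
tRNA_Phe: [TTC, TTT]
tRNA_Pro: [CCA, CCC, CCG, CCT]
tRNA_Ser: [AGC, AGT, TCA, TCC, TCG, TCT]
tRNA_Thr: [ACA, ACC, ACG, ACT]
tRNA_Trp: [TGG]
tRNA_Tyr: [TAC, TAT]
tRNA_Val: [GTA, GTC, GTG, GTT]
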