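subsystem	cellular_process	n_reactions
RNA metabolism	Transcription	3561
RNA metabolism	Transcription regulation	1182
RNA metabolism	mRNA degradation	3646
RNA metabolism	Cleavage of polycistronic mRNA	1029
RNA metabolism	RNA processing	124
RNA metabolism	rRNA modification	864
RNA metabolism	rRNA formation	38
RNA metabolism	tRNA modification	1597
Protein metabolism	Translation	38617
Protein metabolism	tRNA charging	177
Protein metabolism	Aminoacyl-tRNA synthetase charging	33
Protein metabolism	Charging EF-Tu	4
Protein metabolism	tRNA activation (EF-TU)	45
Protein metabolism	Protein maturation	3646
Protein metabolism	Protein folding	2618
Protein metabolism	Metallo-ion binding	128
Protein metabolism	Protein modification	12
Protein metabolism	Protein complex formation	252
Protein metabolism	Protein recycling	1155
Protein metabolism	Ribosomal assembly	13
Protein metabolism	Ribosomal protein modification	21
Protein metabolism	Iron-sulfur cluster incorporation	6
Iron-sulfur metabolism	Iron-sulfur cluster biosynthesis	6
Cellular metabolism	Metabolism	13819
Others	Demands & Sinks	3621
Others	Exchange reactions	375
Total	Total	76589
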