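category	mode	ptc_free	low	moderate	high
old	all	10580	460	74	7
young	all	764	89	32	7
dna_duplication	strict	329	42	18	3
dna_duplication	raw	589	77	30	5
rna_duplication	strict	76	6	0	0
rna_duplication	raw	91	10	0	0
de_novo	strict	84	2	2	2
de_novo	raw	84	2	2	2
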