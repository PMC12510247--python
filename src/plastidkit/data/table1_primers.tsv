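Pair	Forward	F_Location	F_Sequence	F_Length	F_GC	Reverse	R_Location	R_Sequence	R_Length	R_GC	Amplicon_bp	Anneal_C	Target_SNPs
1	F1	218	TTCCCACAACTTTCATACCA	20	40.00	R1	757	CTTTAGGATAAGCGGGTATT	20	40.00	540	51	ycf1_98314
2	F2	277	GTCTGATTGGACCATTTGTA	20	40.00	R2	699	TCAATCTTTATGGGTCCTAC	20	40.00	423	51	ycf2_119153
3	F3	274	TGGTGGAGATGGTGAAGATG	20	50.00	R3	850	AAAGGCCATTAGACTCAGGT	20	45.00	577	53	ycf1_101076,ycf1_101085,ycf1_101094,ycf1_101099,ycf1_101101,ycf1_101103,ycf1_101112,ycf1_101121,ycf1_101130,ycf1_101139,ycf1_101148,ycf1_101157
4	F4	306	GAATATCTAAACCCTGGACT	20	40.00	R4	881	ATTAGCTTCTCCCGAACAGA	20	45.00	576	51	rpoC1_23167
5	F5	251	CTTCTCATTTCCAATCCCTG	20	45.00	R5	770	GAAATGGAAGTTTGGGCTCT	20	45.00	520	53	IGS_23593
6	F6	243	GACCCACATAAGAACAAACG	20	45.00	R6	947	CGGATATGTCCATGATTCACTA	22	40.91	705	53	IGS_50842,IGS_50999
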