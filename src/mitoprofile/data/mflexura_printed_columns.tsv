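gene	size	ign	start_codon	stop_codon
tRNA-Ile	66	0
tRNA-Gln	69	-3
tRNA-Met	68	4
ND2	1035	0	ATG	TAA
tRNA-Trp	69	7
tRNA-Cys	63	-8
tRNA-Tyr	66	6
COI	1545	-8	ATT	TAA
tRNA-Leu(UUR)	67	-5
COII	688	3	ATG	T-
tRNA-Lys	71	0
tRNA-Asp	68	-1
ATP8	159	0	ATT	TAA
ATP6	678	-7	ATG	TAA
COIII	789	-1	ATG	TAA
tRNA-Gly	66	-1
ND3	354	3	ATT	TAG
tRNA-Ala	64	-2
tRNA-Arg	63	0
tRNA-Asn	66	111
tRNA-Ser(AGN)	69	-1
tRNA-Glu	69	-1
tRNA-Phe	65	-2
ND5	1735	0	GTG	T-
tRNA-His	66	0
ND4	1341	3	ATG	TAA
ND4L	297	-7	ATG	TAA
tRNA-Thr	66	2
tRNA-Pro	65	-1
ND6	525	0	ATT	TAA
CytB	1137	-1	ATG	TAG
tRNA-Ser(UCN)	70	-2
ND1	951	86	TTG	TAG
tRNA-Leu(CUN)	66	1
lrRNA	1339	0
tRNA-Val	71	0
srRNA	790	0
CR	735	0
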