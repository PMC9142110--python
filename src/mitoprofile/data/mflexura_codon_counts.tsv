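codon	aa_printed	count
TTT	F	270
TTC	F	51
TTA	L	364
TTG	L	46
CTT	L	102
CTC	L	31
CTA	L	71
CTG	L	12
ATT	I	271
ATC	I	41
ATA	I	153
ATG	M	38
GTT	V	105
GTC	V	28
GTA	V	77
GTG	V	23
TCT	S	95
TCC	S	31
TCA	S	74
TCG	S	12
CCT	P	63
CCC	P	38
CCA	P	42
CCG	P	9
ACT	T	87
ACC	T	27
ACA	T	75
ACG	T	12
GCT	A	92
GCC	A	38
GCA	A	54
GCG	A	24
TAT	Y	109
TAC	Y	48
TAA	*	0
TAG	*	0
CAT	H	58
CAC	H	25
CAA	Q	64
CAG	Q	117
AAT	N	127
AAC	N	23
AAA	K	52
AAG	K	20
GAT	D	52
GAC	D	18
GAA	E	55
GAG	E	24
TGT	C	34
TGC	C	8
TGA	W	87
TGG	W	19
CGT	R	14
CGC	R	7
CGA	R	32
CGG	R	7
AGT	S	45
AGC	S	17
AGA	S	63
AGG	S	3
GGT	G	53
GGC	G	34
GGA	G	83
GGG	G	79
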