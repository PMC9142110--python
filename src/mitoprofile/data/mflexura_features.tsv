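gene	class	strand	start	end	anticodon	anticodon_pos
tRNA-Ile	tRNA	J	1	66	GAT	30-32
tRNA-Gln	tRNA	N	64	132	TTG	100-102
tRNA-Met	tRNA	J	137	204	CAT	167-169
ND2	PCG	J	205	1239
tRNA-Trp	tRNA	J	1247	1315	TCA	1277-1279
tRNA-Cys	tRNA	N	1308	1370	GCA	1339-1341
tRNA-Tyr	tRNA	N	1377	1442	GTA	1409-1411
COI	PCG	J	1435	2979
tRNA-Leu(UUR)	tRNA	J	2975	3041	TAA	3017-3019
COII	PCG	J	3045	3732
tRNA-Lys	tRNA	J	3733	3803	CTT	3763-3765
tRNA-Asp	tRNA	J	3803	3870	GTC	3832-3834
ATP8	PCG	J	3871	4029
ATP6	PCG	J	4023	4700
COIII	PCG	J	4700	5488
tRNA-Gly	tRNA	J	5488	5553	TCC	5517-5519
ND3	PCG	J	5554	5907
tRNA-Ala	tRNA	J	5906	5969	TGC	5935-5937
tRNA-Arg	tRNA	J	5970	6032	TCG	5999-6001
tRNA-Asn	tRNA	J	6144	6209	GTT	6174-6172
tRNA-Ser(AGN)	tRNA	J	6209	6277	GCT	6235-6237
tRNA-Glu	tRNA	J	6277	6345	TTC	6307-6309
tRNA-Phe	tRNA	N	6344	6408	GAA	6376-6378
ND5	PCG	N	6409	8143
tRNA-His	tRNA	N	8144	8209	GTG	8177-8179
ND4	PCG	N	8213	9553
ND4L	PCG	N	9547	9843
tRNA-Thr	tRNA	J	9846	9911	TGT	9877-9879
tRNA-Pro	tRNA	N	9911	9975	TGG	9943-9945
ND6	PCG	J	9977	10501
CytB	PCG	J	10501	11637
tRNA-Ser(UCN)	tRNA	J	11636	11705	TGA	11667-11669
ND1	PCG	N	11792	12742
tRNA-Leu(CUN)	tRNA	N	12744	12809	TAG	12778-12780
lrRNA	rRNA	N	12810	14148
tRNA-Val	tRNA	N	14149	14219	TAC	14184-141186
srRNA	rRNA	N	14220	15009
CR	CR	J	15010	15744
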