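label	pct_T	pct_C	pct_A	pct_G	at_content	at_skew	gc_skew
whole	36.3	12.5	32.3	18.8	68.6	-0.059	0.200
PCGs	39.3	17.1	27.3	16.3	66.6	-0.180	-0.022
PCGs-J	35.6	20.7	29.1	14.7	64.7	-0.101	-0.171
PCGs-N	45.1	11.4	24.4	19.1	69.6	-0.297	0.2552
tRNAs	35.5	12.2	35.4	16.9	70.9	-0.001	0.160
tRNAs-J	34.9	13.9	36.0	15.2	70.9	0.015	0.044
tRNAs-N	36.5	9.2	34.5	19.9	71.0	-0.029	0.368
rRNAs	39.0	10.1	32.9	18.1	71.9	-0.084	0.285
lrRNA	40.4	9.0	33.2	17.4	73.6	-0.097	0.320
srRNA	36.5	12.0	32.3	19.2	68.9	-0.061	0.231
CR	43.6	8.1	41.6	6.7	85.2	-0.023	-0.100
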