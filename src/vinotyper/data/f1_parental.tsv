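# worked-example cross-tabulation: parental genotype-call pairs vs observed F1-hybrid calls
parents	AA	BB	AB	V	N
AA,AA	231536	8	149	900	6311
BB,BB	0	204	1	1	3
AA,BB	8275	8927	156872	1797	12348
BB,AA	4	12	6	0	3
AA,V	12605	19	1681	1578	4445
BB,V	0	10	0	1	0
V,AA	4	0	0	1	0
V,BB	0	9	2	1	1
V,V	3	0	0	11	0
AA,AB	5936	13	6221	190	1345
BB,AB	0	7	1	0	2
AB,AA	52	0	7	0	0
AB,BB	2	1047	467	12	148
AB,AB	6	12	1939	26	75
AA,N	27921	3193	22039	508	6650
BB,N	0	14	0	0	0
AB,N	4	106	136	5	27
V,N	0	4	0	0	0
N,N	36	3	13	0	2
N,AA	267	0	0	1	7
N,BB	3	5	116	0	16
N,AB	3	0	2	0	0
V,AB	0	0	0	1	0
AB,V	0	13	16	6	3
N,V	4	0	0	2	1
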