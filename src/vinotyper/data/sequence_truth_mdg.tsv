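# worked-example cross-tabulation: array calls vs whole-genome-sequence genotype classes, 14 inbred strains
call	AA	BB	Deleted	Inaccessible	Excluded
AA	5488489	5327	88	4818	3504
AB	51460	39080	24	424	1316
BB	7244	1627823	181	3022	6230
V	13510	15488	24	2221	4361
N	43605	48659	19	577	1588
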