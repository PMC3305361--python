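# worked-example cross-tabulation: array calls vs whole-genome-sequence genotype classes, 14 inbred strains
call	AA	BB	Deleted	Inaccessible	Excluded
AA	5523440	7022	63	4673	3456
AB	30970	54075	70	2097	4839
BB	7702	1631208	169	2509	5164
N	42196	44072	34	1783	3540
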