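# worked-example cross-tabulation: array calls vs whole-genome-sequence genotype classes, 14 inbred strains
call	AA	BB	Deleted	Inaccessible	Excluded
AA	5441864	3604	87	4612	3262
AB	97883	46767	34	553	1741
BB	6582	1644208	141	2231	4314
N	57979	41798	74	3666	7682
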