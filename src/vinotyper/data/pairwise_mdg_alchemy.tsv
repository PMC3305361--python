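# worked-example cross-tabulation: two-method genotype calls, 351-sample mouse diversity panel
call	AA	AB	BB	N
AA	127867623	1920909	25627	1026558
AB	769150	16433765	635019	1116810
BB	3425	1257523	29282297	560353
N	931375	1458539	277201	400965
V	132229	76720	63696	513629
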