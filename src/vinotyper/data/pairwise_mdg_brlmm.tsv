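# worked-example cross-tabulation: two-method genotype calls, 351-sample mouse diversity panel
call	AA	AB	BB	N
AA	129030882	824258	20829	964748
AB	1089922	17190764	335325	338733
BB	27880	1628799	29044569	402350
N	1037029	1469896	258170	302985
V	104122	361969	52523	267660
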