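# worked-example cross-tabulation: two-method genotype calls, 351-sample mouse diversity panel
call	AA	AB	BB	N
AA	128281002	675020	16046	731734
AB	1865751	18131854	388169	761682
BB	60277	987808	28913772	321983
N	1082805	1681004	393429	461077
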