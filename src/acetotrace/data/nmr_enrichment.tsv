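time_h	pct_methyl	pct_carbonyl
0	1.0	
4	1.6	
8	2.0	21.8
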