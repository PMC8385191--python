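tumor	Basal-like	HER2-enriched	LuminalA	LuminalB	Normal-like
Basal-like	0	1	1	0	2
HER2-enriched	0	0	0	1	3
LuminalA	1	0	1	1	6
LuminalB	1	0	1	0	5
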