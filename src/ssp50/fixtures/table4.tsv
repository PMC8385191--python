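microarray	Basal-like	HER2-enriched	LuminalA	LuminalB
Basal-like	3	0	0	0
HER2-enriched	1	13	1	0
LuminalA	0	3	5	0
LuminalB	3	0	14	20
UNCLASSIFIED	0	0	1	0
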