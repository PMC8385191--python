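ihc	Basal-like	HER2-enriched	LuminalA	LuminalB	UNCLASSIFIED
HR+/HER2+	0	1	3	16	0
HR+/HER2-	2	1	13	35	1
HR-/HER2+	5	18	3	0	0
HR-/HER2-	7	1	3	0	0
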