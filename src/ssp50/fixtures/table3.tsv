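ihc	Basal-like	HER2-enriched	LuminalA	LuminalB	UNCLASSIFIED
HR+/HER2+	5	8	7	6	0
HR+/HER2-	4	2	41	30	0
HR-/HER2+	5	14	4	1	0
HR-/HER2-	7	3	0	0	1
missing	2	1	3	0	0
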