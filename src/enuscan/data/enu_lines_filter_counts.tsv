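#line	functional_class	total_homozygous	in_dbsnp	in_background
AB5	REPLACEMENT	96	80	13
AB5	SILENT	157	143	12
AB5	UTR	331	191	135
AB5	INTRONIC	106	87	17
AB5	INTERGENIC	54	50	4
M2	REPLACEMENT	43	8	31
M2	SILENT	19	11	7
M2	UTR	73	16	55
M2	INTRONIC	46	18	20
M2	INTERGENIC	40	4	36
X5	REPLACEMENT	128	59	63
X5	SILENT	192	128	63
X5	UTR	387	231	152
X5	INTRONIC	205	116	86
X5	INTERGENIC	89	34	55
Y1	REPLACEMENT	17	1	14
Y1	SILENT	5	0	4
Y1	UTR	14	2	11
Y1	INTRONIC	34	0	31
Y1	INTERGENIC	7	0	7
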