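#line	candidate	wild_type_not_hom_alt	wild_type_hom_alt	mutant_not_hom_alt	mutant_hom_alt
AB5	Rqcd1_L159*	201	0	0	57
M2	Inpp5e_D511G	254	0	0	80
M2	Slc2a6_M99I	254	0	0	80
X5	Rbm12_T556I	161	0	0	55
X5	Dusp15_I157F	159	2	4	51
Y1	Ankrd56_S299P	196	0	0	42
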