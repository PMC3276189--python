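#line	remaining_replacement	within_mapped_region
AB5	3	1
M2	4	2
X5	6	2
Y1	2	1
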