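group	with_overlap	deletion_on_overlap	insertion_on_overlap	deletion_adjacent	insertion_adjacent	total
P493	2	2	0	0	0	2
P787	8	6	1	2	1	9
P995	8	7	0	5	0	10
G900	2	2	0	1	0	2
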