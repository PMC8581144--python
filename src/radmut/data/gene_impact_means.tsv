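group	category	mean	se	hom_mean	hom_se
P493	missense	5.33	0.81	2.17	0.60
P493	in_frame_deletion	1.00	0.24	0.17	0.15
P493	in_frame_insertion	0	0	0	0
P493	start_loss	0	0	0	0
P493	premature_stop	0.17	0.15	0	0
P493	frameshift	2.83	0.83	0.33	0.19
P493	truncation	1.00	0.41	0	0
P493	complete_deletion	11.83	7.04	0.67	0.61
P493	silent	3.17	0.89	0.83	0.15
P787	missense	8.33	0.84	2.5	0.66
P787	in_frame_deletion	0.33	0.19	0.17	0.15
P787	in_frame_insertion	0	0	0	0
P787	start_loss	0.33	0.19	0	0
P787	premature_stop	0.33	0.30	0	0
P787	frameshift	3.33	0.30	1.50	0.31
P787	truncation	2.17	0.55	0.17	0.15
P787	complete_deletion	22.00	19.18	0.17	0.15
P787	silent	2.67	0.69	0.83	0.28
P995	missense	7.33	1.12	2.17	0.15
P995	in_frame_deletion	0.67	0.30	0	0
P995	in_frame_insertion	0	0	0	0
P995	start_loss	0	0	0	0
P995	premature_stop	0.33	0.19	0.33	0.19
P995	frameshift	2.33	0.56	0.5	0.31
P995	truncation	1.50	0.74	0.50	0.31
P995	complete_deletion	1.00	0.62	0.67	0.61
P995	silent	3.67	0.51	0.83	0.28
G900	missense	9.33	1.43	3.83	0.98
G900	in_frame_deletion	0.83	0.28	0	0
G900	in_frame_insertion	0.33	0.19	0	0
G900	start_loss	0.17	0.15	0.17	0.15
G900	premature_stop	0.50	0.20	0	0
G900	frameshift	3.33	0.45	0.83	0.44
G900	truncation	0.67	0.45	0.50	0.46
G900	complete_deletion	0.17	0.15	0	0
G900	silent	4.50	0.91	1.67	0.45
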