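source	dose_gy	lines
proton	494	395
proton	787	362
proton	995	426
gamma	600	490
gamma	900	447
gamma	1200	400
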