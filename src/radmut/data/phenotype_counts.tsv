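category	characteristic	source	dose_gy	count
leaf_color	albino	proton	494	2
leaf_color	albino	proton	787	4
leaf_color	albino	proton	995	1
leaf_color	albino	gamma	600	1
leaf_color	albino	gamma	900	2
leaf_color	albino	gamma	1200	4
leaf_color	low_chlorophyll	proton	494	3
leaf_color	low_chlorophyll	proton	787	2
leaf_color	low_chlorophyll	proton	995	2
leaf_color	low_chlorophyll	gamma	600	5
leaf_color	low_chlorophyll	gamma	900	4
leaf_color	low_chlorophyll	gamma	1200	9
leaf_color	purple_pigmentation	proton	787	1
leaf_color	purple_pigmentation	proton	995	2
leaf_color	purple_pigmentation	gamma	900	3
leaf_color	purple_pigmentation	gamma	1200	3
leaf_color	yellowish	gamma	600	1
leaf_color	variegated	proton	494	1
leaf_color	variegated	proton	787	1
leaf_color	variegated	gamma	900	1
leaf_color	variegated	gamma	1200	1
leaf_color	mottled	proton	787	1
leaf_shape	narrow	proton	494	1
leaf_shape	narrow	proton	787	1
leaf_shape	round	proton	787	1
leaf_shape	round	gamma	900	2
leaf_shape	torpedo	proton	494	1
leaf_shape	curled	proton	995	1
leaf_shape	rolled	proton	787	5
leaf_shape	rolled	proton	995	1
leaf_shape	rolled	gamma	900	2
leaf_shape	rolled	gamma	1200	1
leaf_shape	dentate	proton	787	3
leaf_shape	dentate	proton	995	2
leaf_shape	dentate	gamma	600	2
leaf_shape	larger	proton	995	1
leaf_shape	larger	gamma	600	1
other	extensive_leaf_formation	proton	494	1
other	extensive_leaf_formation	proton	995	2
other	multiple_main_inflorescences	proton	787	1
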