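n_cells	n_drugs	otf_top100	otf_top50	twolevel_top100	twolevel_top50
7	29	13	10	14	12
6	30	15	10	15	14
5	42	16	12	22	20
4	51	14	10	13	8
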