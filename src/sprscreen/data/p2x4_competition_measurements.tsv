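analyte_a	analyte_b	C_a_M	C_b_M	KD_a_M	KD_b_M	RU_a	RU_b	RU_ab	theoretical_competitive_RU	reported_label
BX430	5-BDBD	1e-6	1e-6	4.500E-6	7.795E-6	22.5	34.9	39.3	17.2	non_competitive
CBD	5-BDBD	1e-6	1e-6	1.039E-6	7.795E-6	6.9	5.8	6.9	6.7	competitive
CBV	5-BDBD	1e-6	1e-6	1.638E-5	7.795E-6	0.9	6.4	2.1	4.37	competitive
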