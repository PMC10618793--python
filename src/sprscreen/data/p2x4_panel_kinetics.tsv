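compound	role	k_on_1_per_Ms	k_off_1_per_s	KD_M
BX430	control	1.099E+5	0.4947	4.500E-6
5-BDBD	control	2.882E+4	0.2246	7.795E-6
CBD	cannabinoid	1.922E+4	0.01998	1.039E-6
THCV	cannabinoid	2175	0.03374	1.552E-5
CBGVA	cannabinoid	1892	0.1741	9.200E-5
d8-THCA-A	cannabinoid	1063	0.08122	7.640E-5
CBV	cannabinoid	2474	0.04054	1.638E-5
CBGA	cannabinoid	823.5	0.1186	1.441E-4
CBGV	cannabinoid	8446	0.02626	3.110E-6
CBGOA	cannabinoid	2725	0.3746	1.375E-4
THCA-A	cannabinoid	865.5	0.1009	1.166E-4
CBND	cannabinoid	1522	0.1282	8.420E-5
CBDV	cannabinoid	1.209E+4	0.1198	9.908E-6
11-OH-THC	cannabinoid	1.176E+4	0.07422	6.311E-6
6a-OH-CBD	cannabinoid	1267	0.4273	3.374E-4
CBDAME	cannabinoid	n.d.	n.d.	n.d.
THCB	cannabinoid	n.d.	n.d.	n.d.
CBN	cannabinoid	n.d.	n.d.	n.d.
CBT	cannabinoid	n.d.	n.d.	n.d.
11-nor-9-carboxy-THC	cannabinoid	n.d.	n.d.	n.d.
CBC	cannabinoid	n.d.	n.d.	n.d.
CBDA	cannabinoid	n.d.	n.d.	n.d.
CBCV	cannabinoid	n.d.	n.d.	n.d.
Varinolic acid	cannabinoid	n.d.	n.d.	n.d.
CBL	cannabinoid	n.d.	n.d.	n.d.
CBGM	cannabinoid	n.d.	n.d.	n.d.
CBG	cannabinoid	n.d.	n.d.	n.d.
CBDB	cannabinoid	n.d.	n.d.	n.d.
CBDP	cannabinoid	n.d.	n.d.	n.d.
THCP	cannabinoid	n.d.	n.d.	n.d.
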