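name	v	rho	a	y	E	eta	G
Blood	1584	1060	0.14	1.21
Bone	3198	1990	3.54	0.9
Breast	1510	1020	0.75	1.5
Fat	1430	928	0.6	1
Liver	1578	1050	0.45	1.05
Muscle	1580	1041	0.57	1
Water	1482	1000	2.17e-3	2
PZT-5A	4350	7750			105.8	0.31	40.38
PZT-5H	4560	7500			112.5	0.31	42.94
BaTiO3	5470	5700			119	0.32	45.08
LiNbO3	7360	4640			156.5	0.35	57.96
PMN-PT	4646	8060			121.5	0.32	46.02
PZN-PT	4030	8310			106.8	0.275	41.88
PVDF	2200	1780			7.93	0.18	3.36
PDMS	1430	928	0.6	1
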