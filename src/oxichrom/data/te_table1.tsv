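family	ctrl_mean	kd_mean	prob	log2fc
Alu	3601718.96	3714313.36	1.00	0.04
RNA	2918334.55	3045475.41	0.99	0.06
L1	2837069.25	2730921.52	0.97	-0.06
ERV1	370405.10	353869.12	0.95	-0.07
TcMar-Tigger	239662.63	252421.97	0.87	0.07
UCON19	0.51	1.23	0.76	1.28
UCON18	0.51	1.23	0.76	1.28
hAT-Tip100	34122.72	38990.93	0.76	0.19
ERVK	8958641.10	9448789.20	0.76	0.08
MIR	673530.34	692895.61	0.76	0.04
hAT	12908.30	16757.15	0.76	0.38
TcMar-Mariner	33897.47	38475.09	0.75	0.18
UCON4	234.62	360.51	0.74	0.62
hAT-Charlie	374265.61	380188.93	0.72	0.02
UCON16	6.58	10.85	0.72	0.72
Penelope	7.08	11.83	0.70	0.74
ERVL-MaLR	399009.16	406080.51	0.70	0.03
UCON31	61.20	87.49	0.70	0.52
MER130	15.18	21.75	0.69	0.52
UCON2	320.19	434.63	0.69	0.44
UCON10	7.09	10.93	0.67	0.63
UCON28c	10.12	14.81	0.63	0.55
Eulor4	1.26	1.98	0.55	0.65
UCON12	14.14	4.94	0.52	-1.52
TcMar-Tc2	12524.35	13658.11	0.51	0.13
UCON24	1.27	0.49	0.47	-1.36
UCON17	3.03	1.23	0.46	-1.30
ERVL	174857.94	177852.71	0.44	0.02
MamRep605	7848.87	8610.92	0.41	0.13
UCON28a	201.88	253.61	0.39	0.33
Satellite	28748.18	25760.18	0.37	-0.16
UCON26	532.62	618.38	0.35	0.22
SVA_B	2696.77	3025.33	0.31	0.17
acro	14.16	10.88	0.30	-0.38
UCON11	6.08	3.93	0.29	-0.63
UCON15	4.29	2.25	0.29	-0.93
MuDR	1610.89	1799.90	0.28	0.16
SVA_F	3968.24	4322.50	0.26	0.12
Gypsy	18034.32	16836.16	0.26	-0.10
DNA	5850.42	6284.72	0.25	0.10
Dong-R4	3696.41	3198.15	0.25	-0.21
UCON9	18.69	12.78	0.24	-0.55
Centre	11923.53	12544.21	0.22	0.07
Merlin	297.42	327.87	0.19	0.14
SVA_D	11475.76	11978.90	0.19	0.06
UCON28b	26.33	30.80	0.18	0.23
LTR	1842.20	1987.87	0.18	0.11
UCON8	75.37	65.33	0.15	-0.21
TcMar	8328.59	8597.66	0.11	0.05
SVA_A	1741.04	1827.45	0.10	0.07
CR1	85288.67	84328.51	0.09	-0.02
Helitron	5017.41	5157.97	0.06	0.04
UCON6	1277.83	1325.68	0.06	0.05
RTE	30497.19	29901.20	0.06	-0.03
PiggyBac	4590.52	4349.34	0.06	-0.08
UCON22	12.14	10.47	0.06	-0.21
UCON5	11.14	9.87	0.06	-0.17
telo	489.07	507.40	0.05	0.05
L2	614402.54	610776.39	0.05	-0.01
Deu	2157.42	2220.57	0.05	0.04
hAT-Blackjack	11106.77	11287.96	0.05	0.02
UCON1	3.04	3.25	0.04	0.10
UCON27	72.82	74.65	0.03	0.04
UCON20	12.13	10.95	0.02	-0.15
MamRep564	756.04	712.80	0.02	-0.08
RTE-BovB	1064.66	1011.37	0.02	-0.07
ERV	440.91	422.61	0.01	-0.06
SINE	4912.94	4894.14	0.00	-0.01
UCON25	2.27	2.20	0.00	-0.04
SVA_E	1087.33	1076.64	0.00	-0.01
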