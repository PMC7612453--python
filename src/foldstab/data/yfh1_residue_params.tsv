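residue_label	dH_kcal_mol	dS_kcal_mol_K	dCp_kcal_mol_K	Tm_K	Tc_K	RAD
61 Val	19.9	0.067	1.58	298.4	273.9	48.20
63 Gln	21.1	0.072	2.24	294.0	275.6	3.64
64 Glu	27.7	0.093	3.30	298.0	281.5	2.52
65 Val	24.3	0.081	2.71	299.7	282.2	0.31
68 Leu	21.0	0.071	3.02	296.5	282.8	0.75
70 Leu	28.5	0.096	3.73	298.2	283.1	2.35
71 Glu	29.1	0.097	3.59	299.8	283.9	7.13
72 Lys	33.1	0.111	3.73	299.6	282.2	6.24
75 Glu	24.3	0.081	2.75	300.0	282.7	2.07
76 Glu	17.4	0.058	1.71	300.6	280.8	0.91
78 Asp	29.0	0.096	3.18	301.1	283.2	0.17
83 His	22.8	0.076	2.21	298.4	278.2	0.21
86 Asp	25.4	0.084	2.62	301.0	282.0	0.27
87 Ser	22.8	0.076	2.42	299.1	280.6	0.34
88 Leu	20.2	0.067	1.75	300.6	278.1	0.04
89 Glu	22.1	0.074	2.14	299.7	279.5	0.20
90 Glu	26.1	0.087	2.50	300.9	280.5	0.52
91 Leu	34.1	0.114	4.19	300.3	284.3	0.16
92 Ser	22.6	0.075	1.97	299.7	277.3	0.15
93 Glu	19.5	0.065	1.97	300.1	280.7	0.61
94 Ala	23.6	0.079	2.55	299.6	281.5	4.10
95 His	18.6	0.062	1.31	300.7	273.2	0.28
97 Asp	23.3	0.078	2.52	299.0	280.9	0.95
98 Cys	22.6	0.076	2.59	297.7	280.6	0.26
99 Ile	17.6	0.059	1.75	297.5	277.8	0.11
101 Asp	22.3	0.074	2.42	300.2	282.1	1.08
104 Leu	29.5	0.098	3.12	300.9	282.4	0.78
105 Ser	23.7	0.079	2.51	299.7	281.2	1.18
107 Gly	19.3	0.065	2.44	296.6	281.1	3.58
108 Val	22.3	0.075	2.03	299.0	277.5	0.50
109 Met	26.6	0.089	3.25	299.4	283.3	0.63
110 Thr	33.2	0.111	3.79	300.2	283.0	0.23
112 Glu	28.5	0.094	2.88	301.9	282.5	0.41
113 Ile	17.4	0.059	2.11	297.6	281.3	0.12
115 Ala	15.4	0.052	2.77	295.8	284.9	2.48
116 Phe	14.8	0.049	1.73	298.0	281.3	0.62
117 Gly	27.6	0.093	3.48	298.2	282.6	0.98
119 Tyr	24.9	0.083	2.72	300.3	282.3	0.22
120 Val	15.7	0.053	1.68	297.3	279.0	0.33
127 Asn	23.0	0.077	2.46	297.0	278.7	5.81
128 Lys	15.5	0.052	1.35	300.4	277.9	0.66
129 Gln	14.3	0.048	1.80	296.8	281.2	0.20
130 Ile	27.9	0.093	3.19	300.9	283.8	0.02
131 Trp	21.7	0.073	2.54	298.6	281.8	0.04
132 Leu	26.4	0.088	3.34	300.7	285.1	0.02
133 Ala	24.7	0.082	2.52	299.9	280.7	0.19
134 Ser	20.3	0.068	2.07	299.7	280.5	0.13
136 Leu	13.2	0.044	1.27	299.3	278.9	0.25
140 Asn	25.4	0.085	2.80	299.4	281.6	0.17
142 Phe	20.9	0.070	3.06	299.3	285.8	0.03
143 Asp	21.9	0.073	2.50	300.2	283.1	0.13
146 Asn	23.6	0.080	3.61	295.0	282.1	2.00
147 Gly	25.2	0.085	2.37	297.8	277.0	4.80
148 Glu	21.6	0.072	2.69	298.8	283.0	1.40
150 Val	22.9	0.076	2.20	300.7	280.4	0.03
151 Ser	22.7	0.076	2.39	299.9	281.3	0.05
152 Leu	32.2	0.107	3.87	300.0	283.7	0.16
154 Asn	21.9	0.074	2.40	295.1	277.2	1.14
158 Leu	29.1	0.096	3.11	301.9	283.6	0.03
159 Thr	29.8	0.099	3.38	300.0	282.8	0.09
160 Asp	23.6	0.078	2.55	301.2	283.1	0.28
161 Ile	15.4	0.051	1.66	300.1	281.9	0.09
163 Thr	15.2	0.051	1.44	300.9	280.2	0.15
166 Val	27.3	0.091	2.81	300.8	281.8	0.06
168 Lys	17.3	0.058	1.93	299.9	282.4	0.16
170 Ile	22.6	0.075	2.11	301.3	280.3	0.31
172 Lys	28.1	0.095	3.84	294.1	279.7	1.5
174 Gln	20.6	0.069	2.2	297.5	279.2
131 Trp sc	27.1	0.091	3.21	299.4	282.8
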