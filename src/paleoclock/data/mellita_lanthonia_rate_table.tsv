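# Published divergence table for Mellita and Lanthonia: split age (Ma), percent distance and rate (%/My).
# The identity of the second printed column pair (col2) is not resolvable from the published table;
# its entries are stored verbatim (the second value tracks the age evidently used for the rate cells).
split	age_ma	transisthmian	dist_16S	rate_16S	dist_col2	rate_col2	dist_COI	rate_COI	dist_28S	rate_28S
Lanthonia vs Mellita	5.46	0	33.69	6.17	6.83	5.46	44.93	8.23	0.54	0.10
M.tenuis vs other Mellita	3.83	0	17.32	4.52	6.19	3.83	23.94	6.25	0.18	0.05
(M.sp2,(M.sp1,M.quinquiesperforata)) vs (M.sp6,M.sp5,M.notabilis)	3.21	1	18.45	5.75	6.27	3.21	25.20	7.85	0.11	0.03
M.sp2 vs (M.sp1,M.quinquiesperforata)	3.21	0	9.06	2.82	2.57	3.21	15.03	4.68	0.03	0.01
L.grantii vs (L.sp3,(L.longifissa,L.sp4))	3.12	0	8.34	2.67	2.17	3.12	14.06	4.51	0.10	0.03
L.sp3 vs (L.longifissa,L.sp4)	2.38	0	3.70	1.59	1.26	2.32	6.70	2.89	0.01	0.00
M.sp1 vs M.quinquiesperforata	2.23	0	6.87	3.08	2.87	2.23	10.22	4.58	0.09	0.04
M.sp5 vs M.notabilis	1.88	0	6.52	3.58	2.43	1.82	10.28	5.65	0.02	0.01
M.sp6 vs M.notabilis	1.88	0	8.51	4.68	2.54	1.82	13.56	7.45	0.01	0.01
M.sp5 vs M.sp6	1.88	0	6.70	3.68	3.40	1.82	9.32	5.12	0.01	0.01
L.longifissa vs L.sp4	1.87	0	3.10	1.71	0.69	1.81	5.67	3.13	0.09	0.05
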