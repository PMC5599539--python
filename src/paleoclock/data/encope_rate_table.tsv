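# Published divergence table for Encope: split age (Ma), percent distance and rate (%/My) per gene.
split	age_ma	transisthmian	dist_concatenated	rate_concatenated	dist_16S	rate_16S	dist_COI	rate_COI	dist_ATPase8	rate_ATPase8	dist_ATPase6	rate_ATPase6	dist_28S	rate_28S
(E.aberrans,E.michelini) vs rest	15.15	0	5.10	0.34	4.90	0.32	5.81	0.38	13.77	0.91	9.15	0.60	0.10	0.01
(E.grandis,(E.galapagensis,(E.borealis,E.emarginata))) vs (E.californica,E.micropora)	9.23	0	2.88	0.31	2.57	0.28	2.93	0.32	4.17	0.45	5.87	0.64	0.06	0.01
E.grandis vs (E.galapagensis,(E.borealis,E.emarginata))	8.11	0	2.79	0.34	2.59	0.32	2.96	0.36	3.85	0.47	5.75	0.71	0.06	0.01
E.galapagensis vs (E.borealis,E.emarginata)	6.77	0	1.98	0.29	1.73	0.26	1.94	0.29	3.90	0.58	3.77	0.56	0.09	0.01
E.aberrans vs E.michelini	5.75	0	1.84	0.32	0.97	0.17	5.70	0.99	2.73	0.47	3.97	0.69	0.04	0.01
E.borealis vs E.emarginata	4.90	1	1.55	0.32	0.83	0.17	1.11	0.23	4.39	0.90	3.99	0.81	0.13	0.03
E.californica vs E.micropora	3.88	0	0.60	0.15	0.75	0.19	0.49	0.13	1.89	0.49	1.06	0.27	0.01	0.00
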