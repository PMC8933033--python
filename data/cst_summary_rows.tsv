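cst	kind	Streptococcus salivarius	Prevotella jejuni	Rothia mucilaginosa	Staphylococcus epidermidis	Neisseria subflava	Prevotella melaninogenica	Streptococcus mitis	Staphylococcus aureus	Haemophilus influenzae	Prevotella histicola	Pseudomonas aeruginosa	Tetrasphaera japonica	Corynebacterium propinquum
Ss	average	10.43	0.81	5.59	0.49	0.54	3.06	3.51	1.12	0.25	2.05	0.75	0.21	0.08
Ss	prevalence	92	41	92	5	19	63	79	11	9	51	10	7	2
Pj	average	2.68	9.11	1.10	0.00	2.29	8.95	2.52	0.11	0.03	6.37	0.00	0.01	0.00
Pj	prevalence	81	100	64	0	73	100	84	3	1	95	0	1	0
Rm	average	2.61	0.26	28.08	0.21	3.02	1.40	3.17	0.76	0.18	0.95	0.67	0.13	0.03
Rm	prevalence	69	16	100	4	50	54	66	9	5	32	7	8	1
Se	average	1.09	0.03	0.65	50.12	0.17	0.09	1.46	2.70	0.57	0.03	0.90	1.92	0.24
Se	prevalence	23	4	18	100	7	7	30	29	18	2	25	41	5
Ns	average	1.17	1.78	3.80	0.00	9.26	6.53	3.50	0.07	0.02	1.17	0.00	0.13	0.00
Ns	prevalence	48	65	96	0	100	100	87	4	2	52	0	8	0
Pm	average	2.89	2.09	2.59	0.03	2.72	18.45	3.12	0.75	0.07	4.20	0.03	0.42	0.00
Pm	prevalence	63	88	79	2	73	100	79	4	6	71	2	12	0
Sm	average	1.56	1.02	2.22	0.31	1.54	2.38	22.59	0.03	1.13	0.86	0.00	0.11	0.00
Sm	prevalence	60	28	74	4	40	70	100	4	30	28	0	10	0
Sa	average	1.14	0.10	1.44	1.33	0.07	0.40	1.49	59.58	0.29	0.42	2.27	0.96	0.43
Sa	prevalence	33	6	38	25	4	19	33	100	8	8	27	17	4
Hi	average	2.56	0.59	1.20	1.64	0.53	0.91	2.93	0.85	51.04	1.85	0.00	0.74	0.35
Hi	prevalence	59	31	45	17	24	48	59	7	100	38	0	31	3
Ph	average	2.93	2.79	1.76	0.05	1.15	5.99	3.10	0.07	0.15	16.42	0.06	0.18	0.00
Ph	prevalence	70	74	74	4	44	93	74	4	4	100	4	15	0
Pa	average	1.28	0.41	1.97	0.00	0.00	0.56	0.80	2.14	0.00	0.63	55.84	2.37	0.00
Pa	prevalence	24	19	38	0	0	29	29	24	0	24	100	38	0
Tj	average	0.00	0.84	0.00	0.00	0.25	1.94	1.59	0.00	0.00	0.00	0.15	41.09	0.00
Tj	prevalence	0	11	0	0	6	22	11	0	0	0	6	100	0
Cp	average	0.42	0.00	0.08	2.04	1.69	0.00	0.00	2.63	1.42	0.00	0.00	4.24	50.97
Cp	prevalence	13	0	13	38	25	0	0	25	13	0	0	63	100
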