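no	receptor_residue	ligand_residue	wt_occupancy	wt_sd	dd2_occupancy	dd2_sd
1	E49	S132	0.90	0.02	0.86	0.07
2	T46	Q63	0.86	0.07	0.80	0.14
3	Q47	T127	0.78	0.02	0.76	0.05
4	Q115	S74	0.67	0.02	0.45	0.24
5	Q47	S62	0.62	0.33	0.70	0.14
6	T112	Q63	0.49	0.42	0.40	0.19
7	Y113	G83	0.49	0.07	0.44	0.23
8	R72	E57	0.33	0.57	0.26	0.44
9	R72	D28	0.28	0.49	0.04	0.07
10	S59	R133	0.25	0.38	0.08	0.08
11	E49	R133	0.24	0.42	0.14	0.25
12	K190	E71	0.23	0.22	0.00	0.00
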