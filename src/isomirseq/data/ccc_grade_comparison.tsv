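feature	mean_cpm_a	mean_cpm_b	log2fc_printed	p_value	fdr_bh
hsa-miR-206	5.76	163.17	4.82	0.0452	0.56
hsa-miR-31-3p	3.71	47.59	3.68	0.0455	0.56
hsa-miR-539-5p	11.46	120.21	3.39	0.1733	0.80
hsa-miR-382-5p	42.82	392.61	3.20	0.2301	0.80
hsa-miR-31-5p	443.79	4027.37	3.18	0.0599	0.63
hsa-miR-154-5p	14.26	121.08	3.09	0.3019	0.80
hsa-miR-335-5p	69.42	563.24	3.02	0.0226	0.50
hsa-miR-296-5p	13.30	96.01	2.85	0.0039	0.19
hsa-miR-337-5p	29.08	202.89	2.80	0.1986	0.80
hsa-miR-323b-3p	13.86	95.72	2.79	0.2853	0.80
hsa-miR-379-5p	56.51	370.55	2.71	0.2880	0.80
hsa-miR-133a-3p	4.59	29.96	2.71	0.0210	0.50
hsa-miR-487b-3p	45.91	297.36	2.70	0.3172	0.80
hsa-miR-127-3p	34.01	214.65	2.66	0.3235	0.80
hsa-miR-323a-3p	20.00	121.45	2.60	0.3016	0.80
hsa-miR-376a-5p	19.63	116.84	2.57	0.3179	0.80
hsa-miR-329-3p	18.64	108.40	2.54	0.3207	0.80
hsa-miR-134-5p	65.72	367.31	2.48	0.4159	0.80
hsa-miR-299-5p	20.03	108.46	2.44	0.3034	0.80
hsa-miR-337-3p	55.00	284.17	2.37	0.3529	0.80
hsa-miR-136-5p	39.08	197.20	2.34	0.4154	0.80
hsa-miR-409-3p	112.71	545.22	2.27	0.3481	0.80
hsa-miR-485-3p	14.34	66.37	2.21	0.3792	0.80
hsa-miR-369-5p	12.70	52.10	2.04	0.4218	0.80
hsa-miR-142-5p	3066.08	762.90	-2.01	0.0277	0.50
hsa-miR-378c	1792.81	431.96	-2.05	0.0029	0.19
hsa-miR-20b-5p	397.40	89.68	-2.15	0.0391	0.52
hsa-miR-4284	142.31	30.78	-2.21	0.0801	0.72
hsa-miR-144-3p	1469.84	312.46	-2.23	0.0700	0.67
hsa-miR-144-5p	1064.99	219.75	-2.28	0.0322	0.51
hsa-miR-106a-5p	78.37	16.17	-2.28	0.0142	0.43
hsa-miR-451a	218299.38	36740.32	-2.57	0.0179	0.46
hsa-miR-146a-5p	503.56	76.59	-2.72	0.0039	0.19
hsa-miR-489-3p	495.25	27.07	-4.19	0.0004	0.05
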