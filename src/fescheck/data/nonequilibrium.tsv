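# Nonequilibrium (switching-work) results per benchmark molecule: one-sided
# JAR in both directions, two-sided CRO, block convergence metrics
# (10 blocks), work-distribution moments, one-sided Pi, and the percentage
# overlap of forward and negated-backward work densities.  Rows tagged
# "_5ps" repeat the molecule with 5 ps (5000-step) switches instead of the
# default 1 ps.  Backward dA entries follow the tables' positive-magnitude
# convention.
molecule	jar_fw_delta_a	jar_fw_hyst	jar_fw_sigma_delta_a	jar_fw_mean	jar_fw_sigma	jar_fw_pi	jar_bw_delta_a	jar_bw_hyst	jar_bw_sigma_delta_a	jar_bw_mean	jar_bw_sigma	jar_bw_pi	cro_delta_a	cro_hyst	cro_sigma_delta_a	overlap_percent
1	-305.97	2.92	3.87	-299.85	5.07	-0.80	300.95	0.47	0.39	302.15	1.97	1.60	-301.61	0.53	4.44	32.71
2	-272.53	0.21	0.48	-271.48	0.60	1.86	271.88	0.13	0.48	272.59	1.59	2.19	-271.84	0.09	0.08	53.89
3	-408.69	0.00	0.03	-408.18	0.90	2.40	408.63	0.00	0.05	409.03	0.63	2.57	-408.66	0.00	0.00	56.68
4	-271.25	0.00	0.03	-271.10	0.41	3.02	271.15	0.00	0.02	271.31	0.49	3.00	-271.20	0.00	0.00	79.52
5	-539.16	0.58	0.98	-535.17	1.98	0.08	537.50	2.26	2.71	543.25	3.18	-0.66	-538.78	0.36	0.37	8.76
6	-143.51	3.69	2.10	-137.78	2.08	-0.65	138.57	1.46	2.12	143.83	3.12	-0.47	-140.17	0.41	1.70	23.95
7	-999.40	0.42	0.69	-998.41	0.69	1.91	998.80	1.37	2.82	1000.98	3.29	1.03	-999.02	0.42	0.28	44.88
8	-995.50	3.54	3.79	-990.77	4.06	-0.25	989.35	6.99	4.61	998.13	4.05	-1.69	-995.41	0.90	9.68	24.92
8_5ps	-995.88	2.90	3.74	-991.48	4.16	-0.18	989.36	7.05	3.29	997.91	3.78	-1.71	-995.87	0.68	1.60	27.70
9	-426.22	1.72	1.95	-414.69	8.21	-2.48	415.08	7.74	5.19	428.09	4.12	-2.87	-423.89	0.91	8.28	22.83
9_5ps	-426.53	-0.28	1.04	-419.30	7.09	-1.24	412.65	9.23	5.75	425.23	4.45	-2.95	-425.45	1.22	6.82	60.27
10	-285.45	0.02	0.15	-284.78	0.82	2.25	285.36	0.00	0.03	286.22	1.18	2.03	-285.41	0.01	0.00	46.14
11	-510.05	0.02	0.17	-507.81	2.93	0.99	509.50	0.23	0.41	510.72	0.96	1.68	-509.92	0.03	0.01	44.12
12	-81.64	0.00	0.03	-81.37	0.55	2.78	81.48	0.00	0.03	81.77	0.63	2.73	-81.56	0.00	0.00	72.35
13	-558.93	0.00	0.02	-558.82	0.36	3.13	558.80	0.00	0.01	558.91	0.36	3.12	-558.86	0.00	0.00	84.07
14	-61.10	0.00	0.05	-60.35	0.91	2.08	60.95	-0.01	0.09	61.75	0.99	1.97	-61.03	0.02	0.00	45.35
15	-408.64	0.00	0.02	-408.50	0.39	2.63	408.56	0.00	0.00	408.70	0.42	3.03	-408.59	0.01	0.00	76.59
16	-604.94	1.73	2.59	-600.37	2.46	-0.55	599.77	2.54	0.82	607.38	4.70	-1.37	-602.79	0.52	2.78	33.53
17	-672.92	0.00	0.02	-672.79	0.38	3.08	672.88	0.00	0.01	673.01	0.41	3.07	-672.90	0.00	0.00	76.92
18	-533.65	2.30	2.30	-527.81	2.42	-0.69	529.28	2.69	3.09	536.11	5.43	-1.05	-530.42	0.61	3.72	26.08
19	-912.05	4.65	3.21	-904.31	3.36	-1.53	906.22	0.00	0.81	909.91	3.03	0.05	-907.05	0.45	1.40	25.82
20	-704.48	2.63	4.45	-699.99	4.35	-0.18	697.46	5.67	3.51	706.31	2.49	-1.72	-704.26	0.77	7.32	13.21
21	-55.94	1.36	1.40	-53.45	1.12	0.82	53.51	-0.02	0.04	54.19	1.09	2.05	-53.70	0.09	0.53	60.60
22	-172.40	6.19	3.39	-162.42	1.51	-2.45	165.24	0.37	0.78	171.36	7.48	-0.80	-165.13	0.11	0.20	9.71
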