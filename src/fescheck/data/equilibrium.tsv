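# Equilibrium (instantaneous energy-gap) results per benchmark molecule:
# one-sided FEP in both directions, two-sided BAR, block convergence
# metrics (10 blocks), distribution moments, one-sided Pi, and the
# percentage overlap of forward and negated-backward dU densities.
# Backward dA entries follow the tables' positive-magnitude convention.
molecule	fep_fw_delta_a	fep_fw_hyst	fep_fw_sigma_delta_a	fep_fw_mean	fep_fw_sigma	fep_fw_pi	fep_bw_delta_a	fep_bw_hyst	fep_bw_sigma_delta_a	fep_bw_mean	fep_bw_sigma	fep_bw_pi	bar_delta_a	bar_hyst	bar_sigma_delta_a	overlap_percent
1	-301.11	4.08	5.29	-282.47	7.89	-3.14	305.82	1.87	2.02	322.87	7.30	-3.29	-303.34	-0.15	3.15	0.04
2	-255.52	0.19	0.51	-245.10	4.29	-1.15	258.88	0.29	0.60	268.72	5.28	-1.47	-256.87	-0.05	0.11	0.28
3	-412.88	0.35	0.65	-402.47	3.49	-1.17	416.38	0.54	0.78	428.26	4.86	-2.06	-414.19	-0.01	0.01	0.12
4	-254.51	0.43	0.69	-239.09	5.66	-2.43	259.24	0.51	0.84	269.67	4.34	-1.64	-256.34	0.00	0.03	0.06
5	-589.94	2.30	2.38	-570.06	5.78	-3.41	604.61	2.25	2.49	626.49	7.84	-4.29	-596.97	0.48	0.25	0.00
6	-109.58	2.58	2.59	-86.31	7.14	-4.07	130.57	4.83	4.41	162.27	10.42	-6.04	-118.33	0.56	2.35	0.00
7	-992.13	0.33	0.67	-982.02	3.94	-1.06	994.96	4.83	12.05	1011.88	19.05	-3.26	-993.15	0.21	0.49	0.28
8	-994.00	4.16	4.03	-982.45	4.39	-1.46	988.29	9.09	5.74	1009.22	7.77	-4.10	-992.02	1.03	14.08	3.72
9	-447.42	2.99	3.12	-423.12	9.04	-4.27	451.15	8.94	4.93	475.54	6.40	-4.77	-449.44	1.02	5.61	0.02
10	-336.30	0.84	0.99	-320.41	5.46	-2.54	341.91	0.31	0.72	352.24	4.10	-1.61	-337.98	0.11	0.07	0.04
11	-460.25	1.37	1.30	-441.09	7.09	-3.26	464.90	1.43	1.15	482.37	8.89	-3.38	-461.88	0.11	0.07	0.02
12	-70.74	2.17	1.31	-54.33	4.82	-2.66	84.97	0.85	1.21	115.59	11.07	-5.86	-77.20	0.25	0.02	0.00
13	-556.49	2.79	1.67	-547.25	5.39	-3.27	571.83	1.37	1.32	587.80	5.62	-3.28	-567.59	0.18	0.15	0.01
14	-80.28	0.79	0.97	-65.97	4.62	-2.17	85.55	0.78	0.77	100.32	6.15	-2.89	-82.62	0.12	0.10	0.03
15	-406.76	0.18	0.46	-398.31	3.39	-0.56	408.29	0.32	0.54	419.87	5.52	-2.04	-407.59	0.02	0.00	0.51
16	-633.17	1.32	1.57	-621.65	4.28	-1.45	638.22	2.26	2.73	664.09	8.08	-5.12	-636.14	0.72	0.68	0.05
17	-673.11	0.21	0.55	-664.21	3.29	-0.70	672.67	-0.13	0.71	682.01	3.11	-1.71	-673.41	-0.03	0.01	0.69
18	-518.20	1.82	1.80	-501.32	5.34	-2.76	525.15	4.99	4.91	551.31	9.84	-5.09	-520.79	0.90	3.94	0.10
19	-879.27	3.54	2.13	-857.72	6.10	-3.74	892.96	1.86	2.43	918.55	9.50	-4.99	-885.39	0.51	0.21	0.00
20	-691.39	3.08	4.83	-676.22	6.43	-2.37	713.26	0.83	1.34	753.13	14.99	-7.29	-702.33	0.83	1.13	0.00
21	-70.62	2.52	1.58	-59.20	3.66	-1.43	69.86	1.10	1.30	87.37	8.66	-3.39	-69.33	0.25	0.84	0.37
22	-177.51	0.73	0.97	-165.15	4.25	-1.68	181.81	0.82	1.04	213.38	37.01	-6.02	-179.19	0.14	0.22	0.07
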