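# Per-molecule records of the 22-molecule gas-phase MM->SCC-DFTB/3ob benchmark:
# ZINC database id, atom counts, force-field generation penalties, and the
# constant free-energy offset (kcal/mol) split off from every tabulated dA.
molecule	zinc_id	n_atoms_total	n_heavy	param_penalty	charge_penalty	offset
1	00061095	36	21	432.10	200.99	29000
2	00077329	16	10	378.50	347.24	15000
3	00079729	18	13	683.00	207.72	17000
4	00086442	21	12	312.50	283.62	19000
5	00087557	31	17	378.50	347.31	25000
6	00095858	25	16	567.90	361.40	25000
7	00107550	21	11	378.50	347.29	16000
8	00107778	22	15	378.50	347.29	21000
9	00123162	34	21	385.50	217.28	29000
10	00133435	34	22	470.50	27.14	28000
11	00138607	36	20	336.00	261.56	29000
12	00140610	20	12	449.00	214.90	17000
13	00164361	23	14	424.00	194.49	20000
14	00167648	44	26	436.50	226.60	35000
15	00169358	26	16	540.40	142.16	22000
16	01755198	28	12	329.00	21.11	19000
17	01867000	32	18	470.50	5.82	22000
18	03127671	41	24	329.00	25.20	34000
19	04344392	52	29	329.00	24.78	40000
20	04363792	28	21	698.00	185.49	28000
21	06568023	30	18	329.00	21.60	25000
22	33381936	33	21	545.50	395.62	30000
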