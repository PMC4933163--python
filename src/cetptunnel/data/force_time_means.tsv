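# Steered-transfer times of a cholesteryl ester pulled through the CETP
# tunnel: published mean ± sample SD over four replicate all-atom
# simulations at each of 18 constant driving forces.
force_kcal_mol_A	mean_time_ns	sd_time_ns	n
6	4.98	1.94	4
7	2.93	0.57	4
8	1.58	0.30	4
9	1.08	0.12	4
10	0.66	0.06	4
11	0.54	0.06	4
12	0.51	0.13	4
13	0.35	0.06	4
14	0.28	0.02	4
15	0.24	0.01	4
16	0.21	0.02	4
17	0.18	0.01	4
18	0.16	0.01	4
19	0.15	0.01	4
20	0.14	0.01	4
21	0.13	0.01	4
22	0.11	0.01	4
23	0.10	0.01	4
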