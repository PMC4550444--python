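# Published base composition and skewness of 17 lepidopteran mitogenomes,
# by genome partition. Percentages and skews are kept exactly as printed;
# the skew columns are the authors' values (a few cells disagree with
# arithmetic on the same row's printed percentages at the third decimal).
species	partition	size_bp	pct_A	pct_G	pct_T	pct_C	at_pct	at_skew	gc_skew
C_menciana	whole	15369	41.28	7.61	38.78	12.32	80.06	0.031	-0.236
A_ipsilon	whole	15377	40.38	7.71	40.87	11.04	81.25	-0.006	-0.178
L_dispar	whole	15569	40.58	7.57	39.30	12.55	79.88	0.016	-0.248
H_cunea	whole	15481	40.58	7.55	39.81	12.06	80.39	0.010	-0.230
A_formosae	whole	15453	38.67	7.53	40.83	12.98	79.49	-0.027	-0.266
O_lunifer	whole	15593	40.09	7.56	37.75	14.60	77.84	0.030	-0.318
P_flavescens	whole	15659	40.07	7.87	40.80	11.26	80.87	-0.009	-0.177
B_mandarina	whole	15682	43.11	7.40	38.48	11.01	81.59	0.057	-0.196
A_selene	whole	15236	38.54	8.05	40.37	13.03	78.91	-0.023	-0.236
A_pernyi	whole	15566	39.22	7.77	40.94	12.07	80.16	-0.021	-0.216
E_pyretorum	whole	15327	39.17	7.63	41.65	11.55	80.82	-0.031	-0.204
T_hypsalis	whole	15329	40.00	7.67	41.42	10.92	81.41	-0.017	-0.175
L_haraldusalis	whole	15213	40.47	7.66	41.04	10.83	81.52	-0.007	-0.172
C_pomonella	whole	15253	39.92	7.88	40.21	11.99	80.13	-0.004	-0.207
G_dimorpha	whole	15831	39.99	7.77	40.85	11.39	80.84	-0.011	-0.189
L_taibai	whole	15553	40.37	7.39	41.10	11.14	81.46	-0.009	-0.202
A_ilia	whole	15242	39.77	7.75	40.68	11.80	80.45	-0.011	-0.207
C_menciana	PCG	11190	40.68	8.40	37.72	13.20	78.42	0.038	-0.222
A_ipsilon	PCG	11226	39.69	8.44	40.14	11.72	79.83	-0.006	-0.163
L_dispar	PCG	11227	39.67	8.44	38.16	13.73	77.83	0.019	-0.239
H_cunea	PCG	11198	39.98	8.35	38.61	13.06	78.59	0.017	-0.220
A_formosae	PCG	11217	38.18	8.28	39.62	13.92	77.80	-0.019	-0.254
O_lunifer	PCG	11266	32.47	12.08	43.26	12.19	75.73	-0.142	-0.004
P_flavescens	PCG	11206	39.40	8.90	39.56	12.15	78.96	-0.002	-0.154
B_mandarina	PCG	11196	42.83	8.26	37.04	11.87	79.87	0.072	-0.179
A_selene	PCG	11231	37.93	8.74	39.44	13.89	77.37	-0.020	-0.228
A_pernyi	PCG	11204	39.22	7.77	40.94	12.07	80.16	-0.021	-0.216
E_pyretorum	PCG	11228	33.18	10.50	46.23	10.09	79.41	-0.164	0.020
T_hypsalis	PCG	11188	39.31	8.46	40.66	11.57	79.97	-0.017	-0.155
L_haraldusalis	PCG	11193	39.88	8.47	40.16	11.49	80.04	-0.003	-0.151
C_pomonella	PCG	11199	39.55	8.69	39.00	12.76	78.55	0.007	-0.190
G_dimorpha	PCG	11232	39.51	8.81	39.18	12.49	78.69	0.004	-0.173
L_taibai	PCG	11178	39.56	8.26	40.18	12.01	79.74	-0.008	-0.185
A_ilia	PCG	11148	39.41	8.41	39.49	12.69	78.89	-0.001	-0.203
C_menciana	tRNA	1472	42.12	7.81	40.01	10.05	82.13	0.026	-0.125
A_ipsilon	tRNA	1465	41.23	8.12	40.48	10.17	81.71	0.014	-0.112
L_dispar	tRNA	1459	41.60	7.95	39.48	10.97	81.08	0.026	-0.160
H_cunea	tRNA	1463	41.83	7.86	39.99	10.32	81.82	0.022	-0.135
A_formosae	tRNA	1457	40.43	7.96	40.36	11.26	80.78	0.001	-0.172
O_lunifer	tRNA	1666	41.78	7.32	39.86	11.04	81.63	0.023	-0.202
P_flavescens	tRNA	1474	41.66	7.80	40.64	9.91	82.29	0.012	-0.119
B_mandarina	tRNA	1472	41.78	7.81	39.95	10.46	81.73	0.022	-0.145
A_selene	tRNA	1459	40.37	8.16	40.23	11.24	80.60	0.002	-0.159
A_pernyi	tRNA	1459	39.22	7.77	40.94	12.07	80.16	-0.021	-0.216
E_pyretorum	tRNA	1424	42.59	10.61	39.35	7.45	81.94	0.039	0.174
T_hypsalis	tRNA	1456	40.73	7.90	41.35	10.03	82.07	-0.008	-0.119
L_haraldusalis	tRNA	1451	41.08	7.86	41.42	9.65	82.49	-0.004	-0.102
C_pomonella	tRNA	1451	41.14	7.93	40.32	10.61	81.46	0.010	-0.145
G_dimorpha	tRNA	1451	41.01	8.06	40.52	10.41	81.53	0.006	-0.127
L_taibai	tRNA	1440	41.39	7.85	40.90	9.86	82.29	0.006	-0.113
A_ilia	tRNA	1433	40.61	8.30	40.96	10.12	81.58	-0.004	-0.099
C_menciana	rRNA	2137	42.82	4.73	40.99	11.46	83.81	0.022	-0.416
A_ipsilon	rRNA	2162	41.58	5.00	43.57	9.85	85.15	-0.023	-0.327
L_dispar	rRNA	2150	42.79	4.79	41.81	10.60	84.60	0.012	-0.377
H_cunea	rRNA	2234	42.08	4.92	42.75	10.25	84.83	-0.008	-0.351
A_formosae	rRNA	2163	38.93	4.72	44.85	11.51	83.77	-0.071	-0.418
O_lunifer	rRNA	2157	41.96	4.82	40.19	13.03	82.15	0.022	-0.460
P_flavescens	rRNA	2198	41.31	4.73	44.04	9.92	85.35	-0.032	-0.354
B_mandarina	rRNA	2134	43.86	4.78	41.05	10.31	84.91	0.028	-0.366
A_selene	rRNA	2126	39.93	4.99	43.79	11.29	83.73	-0.046	-0.387
A_pernyi	rRNA	2144	39.22	7.77	40.94	12.07	80.16	-0.021	-0.216
E_pyretorum	rRNA	2116	41.16	4.82	43.38	10.63	84.55	-0.026	-0.376
T_hypsalis	rRNA	2156	42.02	4.92	43.09	9.97	85.11	-0.013	-0.339
L_haraldusalis	rRNA	2121	42.20	4.67	43.33	9.81	85.53	-0.013	-0.355
C_pomonella	rRNA	2147	40.48	5.03	43.92	10.57	84.40	-0.041	-0.355
G_dimorpha	rRNA	2181	41.13	4.95	43.83	10.09	84.96	-0.032	-0.342
L_taibai	rRNA	1805	42.16	5.37	41.83	10.64	83.99	0.004	-0.329
A_ilia	rRNA	2109	40.11	4.98	44.86	10.05	84.97	-0.056	-0.337
C_menciana	control	372	44.35	2.42	50.00	3.23	94.35	-0.060	-0.143
A_ipsilon	control	332	46.08	1.51	48.80	3.61	94.88	-0.029	-0.410
L_dispar	control	435	40.58	7.57	39.30	12.55	79.88	0.016	-0.248
H_cunea	control	357	45.66	1.12	49.30	3.92	94.96	-0.038	-0.556
A_formosae	control	482	42.95	2.90	49.79	4.36	92.74	-0.074	-0.201
O_lunifer	control	319	44.5	1.6	48.9	5.0	93.4	-0.047	-0.524
P_flavescens	control	541	42.14	2.22	49.72	5.91	91.87	-0.083	-0.454
B_mandarina	control	484	46.49	2.69	47.93	2.89	94.42	-0.015	-0.036
A_selene	control	339	43.07	5.90	44.84	6.19	87.91	-0.020	-0.024
A_pernyi	control	552	39.22	7.77	40.94	12.07	80.16	-0.021	-0.216
E_pyretorum	control	358	42.18	2.51	50.00	5.31	92.18	-0.085	-0.358
T_hypsalis	control	350	43.43	1.14	52.00	3.43	95.43	-0.090	-0.501
L_haraldusalis	control	310	45.81	0.97	50.32	2.90	96.13	-0.047	-0.499
C_pomonella	control	351	43.30	1.14	52.42	3.13	95.73	-0.095	-0.466
G_dimorpha	control	848	41.63	1.30	54.83	2.24	96.46	-0.137	-0.266
L_taibai	control	939	45.15	1.70	49.41	3.73	94.57	-0.045	-0.374
A_ilia	control	403	42.93	3.23	49.63	4.22	92.56	-0.072	-0.133
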