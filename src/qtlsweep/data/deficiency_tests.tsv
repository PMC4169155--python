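deletion	balancer	mean_E_def	sd_E_def	mean_E_bal	sd_E_bal	mean_A_def	sd_A_def	mean_A_bal	sd_A_bal	delta_def	delta_bal	p_L	p_G	p_LxG	stock_no
Df(1)BSC351	FM7h	31.70	7.99	30.91	7.88	31.46	9.42	32.73	8.72	0.24	-1.82	0.070057	0.838897	0.343401	24375
Df(1)BSC882	FM7h	29.39	9.94	30.91	7.88	32.69	12.41	32.73	8.72	-3.3	-1.82	0.018773	0.149609	0.574953	30587
Df(1)HA32	FM7c	37.75	8.24	32.16	9.01	41.61	10.42	33.25	9.28	-3.86	-1.09	0.177930	0.000001	0.454433	947
Df(1)ED6906	FM7h	26.93	5.66	30.91	7.88	36.28	8.52	32.73	8.72	-9.35	-1.82	0.000103	0.779708	0.000289	8955
Df(1)BSC711	FM7h	35.73	6.52	30.91	7.88	34.03	8.45	32.73	8.72	1.7	-1.82	0.944120	0.011307	0.121501	26563
Df(1)BSC536	FM7h	36.27	9.81	30.91	7.88	36.43	11.34	32.73	8.72	-0.16	-1.82	0.055280	0.002486	0.473532	25064
Df(1)BSC622	Binsinscy	33.37	9.22	35.59	8.83	34.50	8.65	36.60	9.59	-1.13	-1.01	0.386305	0.121365	0.820123	25697
Df(1)C128	FM6	26.97	6.16	30.11	8.63	37.44	8.11	32.63	7.74	-10.48	-2.52	0.000012	0.606252	0.000885	949
Df(1)BSC866	Binsinscy	36.26	8.16	35.59	8.83	37.46	11.06	36.60	9.59	-1.21	-1.01	0.480645	0.501206	0.850165	29989
Df(1)BSC662	Binsinscy	40.29	8.98	35.59	8.83	39.89	9.70	36.60	9.59	0.39	-1.01	0.330040	0.002076	0.615274	26514
Df(1)BSC592	Binsinscy	31.42	7.47	35.59	8.83	37.92	9.16	36.60	9.59	-6.51	-1.01	0.063548	0.639100	0.031094	25426
Df(1)Exel6241	FM7c	31.57	7.29	32.16	9.01	30.29	8.76	33.25	9.28	1.29	-1.09	0.685768	0.224516	0.294193	7715
Df(1)ED6957	FM7j	27.90	7.68	32.16	9.01	29.21	6.77	33.25	9.28	-1.31	-1.09	0.261153	0.001693	0.795931	8033
Df(1)BSC537	FM7h	29.64	7.36	30.91	7.88	35.36	8.17	32.73	8.72	-5.71	-1.82	0.004959	0.528960	0.099098	25065
Df(1)BSC712	FM7j	40.21	8.39	35.59	8.83	39.66	9.36	36.60	9.59	0.55	-1.01	0.623921	0.005147	0.565518	26564
Df(1)BSC539	Binsinscy	31.50	7.07	35.59	8.83	34.30	7.52	36.60	9.59	-2.8	-1.01	0.239470	0.026941	0.414266	25067
Df(1)ED7005	FM7h	29.63	6.45	30.91	7.88	29.21	6.46	32.73	8.72	0.43	-1.82	0.060255	0.075504	0.350039	9153
Df(1)BSC755	Binsinscy	30.36	7.49	30.11	8.63	33.33	6.92	32.63	7.74	-2.98	-2.52	0.009057	0.547656	0.88738	26853
Df(1)BSC540	FM7h	32.20	7.51	30.91	7.88	34.73	9.31	32.73	8.72	-2.53	-1.82	0.022620	0.141156	0.845784	25068
Df(1)BSC572	FM7h	31.11	6.04	30.91	7.88	37.05	7.54	32.73	8.72	-5.94	-1.82	0.009129	0.070999	0.152617	25391
Df(1)BSC287	Binsinscy	36.11	9.57	35.59	8.83	35.23	8.06	36.60	9.59	0.87	-1.01	0.596120	0.852371	0.643564	23672
Df(1)ED7067	FM7h	28.89	7.99	30.91	7.88	29.58	7.80	32.73	8.72	-0.68	-1.82	0.039538	0.029350	0.702833	9154
Df(1)Exel6242	FM7c	33.96	7.48	32.16	9.01	32.93	7.68	33.25	9.28	1.03	-1.09	0.585559	0.397537	0.406384	7716
Df(1)ED7147	FM7h	31.43	7.44	30.91	7.88	34.96	8.42	32.73	8.72	-3.52	-1.82	0.010630	0.272976	0.497331	9171
Df(1)BSC543	FM7h	30.88	6.43	30.91	7.88	33.75	6.67	32.73	8.72	-2.88	-1.82	0.012423	0.689596	0.674376	25071
Df(1)ED7153	FM7h	29.80	6.30	30.91	7.88	30.47	6.82	32.73	8.72	-0.67	-1.82	0.028176	0.134114	0.603622	8953
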