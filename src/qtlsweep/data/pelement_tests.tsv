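pelement	balancer	mean_E_def	sd_E_def	mean_E_bal	sd_E_bal	mean_A_def	sd_A_def	mean_A_bal	sd_A_bal	delta_def	delta_bal	p_L	p_G	p_LxG	stock_no
P(EPgy2)CG1677EY06475	FM7a	29.28	8.92	31.32	9.48	29.96	8.73	32.44	10.16	-0.67	-1.12	0.38070	0.02130	0.83404	17545
P(EPgy2)unc-119EY20221	FM7a	27.99	7.83	31.32	9.48	31.78	9.28	32.44	10.16	-3.79	-1.12	0.01166	0.02542	0.15217	22375
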