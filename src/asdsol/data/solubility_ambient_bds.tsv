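# pressure_MPa = 0.1
# method = BDS
# system = nimesulide + Kollidon VA64, annealed from 40 wt% polymer supersaturated mix
temperature_K	tg_K	tg_err_K	wtpct_drug	wtpct_err
368	343	1.1	32	0.9
373	342	1.0	33	0.8
378	341	0.9	35	0.8
383	339	0.8	37	0.6
388	336	0.8	41	0.5
393	334	0.7	45	0.4
398	330	0.6	49	0.4
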