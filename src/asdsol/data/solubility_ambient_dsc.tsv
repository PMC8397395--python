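# pressure_MPa = 0.1
# method = DSC
# system = nimesulide + Kollidon VA64, annealed from 40 wt% polymer supersaturated mix
temperature_K	tg_K	tg_err_K	wtpct_drug	wtpct_err
368	344	0.5	32	0.2
373	343	0.5	33	0.2
378	342	0.5	35	0.2
383	340	0.5	37	0.2
388	337	0.5	41	0.2
393	335	0.5	45	0.3
398	330	0.5	49	0.2
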