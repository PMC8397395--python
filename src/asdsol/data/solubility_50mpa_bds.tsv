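# pressure_MPa = 50
# method = BDS
# system = nimesulide + Kollidon VA64, annealed from 40 wt% polymer supersaturated mix
temperature_K	tg_K	tg_err_K	wtpct_drug	wtpct_err
368	358	2.1	29	1.4
378	357	2.1	31	1.4
388	356	1.7	32	1.1
398	354	1.5	36	1.0
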