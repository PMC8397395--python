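# pressure_MPa = 0.1
# method = DSC
# note = calorimetric Tg (heat-capacity step midpoint, 10 K/min)
wtpct_poly	tg_K
0	294
20	303
30	312
40	321
55	335
80	355
100	377
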