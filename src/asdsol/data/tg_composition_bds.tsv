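# pressure_MPa = 0.1
# method = BDS
# note = dielectric Tg (VFT extrapolation to tau_alpha = 100 s)
wtpct_poly	tg_K
0	291
20	302
30	311
40	320
55	334
80	354
100	376
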