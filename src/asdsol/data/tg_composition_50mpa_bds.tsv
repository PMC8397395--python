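# pressure_MPa = 50
# method = BDS
# note = dielectric Tg at 50 MPa for the compositions also measured at ambient pressure
wtpct_poly	tg_K
20	314
40	332
55	346
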