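{
  "system": "nimesulide (NMS) + Kollidon VA64 (KVA)",
  "tm0_K": 421.0,
  "tm0_50MPa_K": 435.0,
  "dhfus_J_per_mol": 32988.0,
  "d_drug_g_per_cm3": 1.41,
  "d_poly_g_per_cm3": 1.20,
  "mw_drug_g_per_mol": 308.3,
  "mw_poly_g_per_mol": 46000.0
}
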