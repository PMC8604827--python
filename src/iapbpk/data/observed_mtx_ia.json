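{
  "description": "Observed PK metrics after a single 5 mg IA methotrexate dose in RA patients; plasma values converted from blood via Rbp = 0.79.",
  "dose_mg": 5.0,
  "plasma": {"cmax_ng_ml": 108.3, "auc_0_25_ng_h_ml": 960.6, "tmax_h": 2.02},
  "synovial_fluid": {"cmax_ug_ml": 228.0, "auc_0_25_ug_h_ml": 270.8}
}
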