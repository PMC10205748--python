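{
  "description": "Fitted competition-model parameters for four reference melanoma patients (serologic-marker burden, IU/L-equivalents), with the published effective-dose-window bounds (per day) carried verbatim alongside.",
  "patients": [
    {"patient_id": 2, "r": 0.1318, "K": 580.8725, "delta": 0.0890, "c": 2.2920, "edw_lower": 0.0503, "edw_upper": 0.0743},
    {"patient_id": 6, "r": 0.1815, "K": 798.6885, "delta": 0.1376, "c": 3.1830, "edw_lower": 0.0276, "edw_upper": 0.1245},
    {"patient_id": 7, "r": 0.1829, "K": 663.0487, "delta": 0.1283, "c": 2.3628, "edw_lower": 0.1040, "edw_upper": 0.1055},
    {"patient_id": 8, "r": 0.1655, "K": 544.2614, "delta": 0.0968, "c": 1.7348, "edw_lower": 0.001, "edw_upper": 0.0701}
  ]
}
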