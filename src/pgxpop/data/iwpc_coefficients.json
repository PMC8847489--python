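{
  "version": "IWPC pharmacogenetic algorithm (2009), sqrt(mg/week) scale",
  "terms": {
    "intercept": 5.6044,
    "age_decades": -0.2614,
    "height_cm": 0.0087,
    "weight_kg": 0.0128,
    "vkorc1_GA": -0.8677,
    "vkorc1_AA": -1.6974,
    "vkorc1_unknown": -0.4854,
    "cyp2c9_1_2": -0.5211,
    "cyp2c9_1_3": -0.9357,
    "cyp2c9_2_2": -1.0616,
    "cyp2c9_2_3": -1.9206,
    "cyp2c9_3_3": -2.3312,
    "cyp2c9_unknown": -0.2188,
    "race_asian": -0.1092,
    "race_black_african_american": -0.2760,
    "race_missing_or_mixed": -0.1032,
    "enzyme_inducer": 1.1816,
    "amiodarone": -0.5503
  }
}
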