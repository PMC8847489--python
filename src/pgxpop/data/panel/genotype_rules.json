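{
  "VKORC1": [
    {"target": "16:31107689:G:A:rs9923231", "genotype": "HOM_ALT", "phenotype": "Lower dosage requirement", "ehr_priority": "Abnormal/Priority/High Risk"},
    {"target": "16:31107689:G:A:rs9923231", "genotype": "HET", "phenotype": "Lower dosage requirement", "ehr_priority": "Abnormal/Priority/High Risk"}
  ],
  "IFNL3": [
    {"target": "19:39738787:C:T:rs12979860", "genotype": "HOM_ALT", "phenotype": "Unfavourable response", "ehr_priority": "Abnormal/Priority/High Risk"},
    {"target": "19:39738787:C:T:rs12979860", "genotype": "HET", "phenotype": "Unfavourable response", "ehr_priority": "Abnormal/Priority/High Risk"}
  ],
  "RYR1": [
    {"target": "19:38958362:C:T:rs111888148", "genotype": "CARRIER_ANY", "phenotype": "Malignant Hyperthermia Susceptibility", "ehr_priority": "Abnormal/Priority/High Risk"},
    {"target": "19:38987119:G:A:rs193922762", "genotype": "CARRIER_ANY", "phenotype": "Malignant Hyperthermia Susceptibility", "ehr_priority": "Abnormal/Priority/High Risk"}
  ],
  "CACNA1S": [
    {"target": "1:201061121:G:A:rs772226819", "genotype": "CARRIER_ANY", "phenotype": "Malignant Hyperthermia Susceptibility", "ehr_priority": "Abnormal/Priority/High Risk"},
    {"target": "1:201008640:C:T:rs1800559", "genotype": "CARRIER_ANY", "phenotype": "Malignant Hyperthermia Susceptibility", "ehr_priority": "Abnormal/Priority/High Risk"}
  ],
  "HLA-A*31:01": [
    {"target": "HLA-A*31:01", "genotype": "CARRIER_ANY", "phenotype": "Risk of SJS/TEN", "ehr_priority": "Abnormal/Priority/High Risk"}
  ],
  "HLA-B*15:02": [
    {"target": "HLA-B*15:02", "genotype": "CARRIER_ANY", "phenotype": "Risk of SJS/TEN", "ehr_priority": "Abnormal/Priority/High Risk"}
  ],
  "HLA-B*57:01": [
    {"target": "HLA-B*57:01", "genotype": "CARRIER_ANY", "phenotype": "Hypersensitivity risk", "ehr_priority": "Abnormal/Priority/High Risk"}
  ],
  "HLA-B*58:01": [
    {"target": "HLA-B*58:01", "genotype": "CARRIER_ANY", "phenotype": "Risk of SCAR", "ehr_priority": "Abnormal/Priority/High Risk"}
  ]
}
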