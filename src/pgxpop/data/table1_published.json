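{
  "description": "Published cohort-level actionability summary: per-category actionable genotype/diplotype counts in the Qatari cohort (n=6045) and combined per-row totals for the Qatari and 1000 Genomes (n=2504) cohorts. Inputs to aggregation and two-group comparison; no individual-level data.",
  "qgp_n": 6045,
  "kg_n": 2504,
  "categories": [
    {"row": "CACNA1S", "category": "Malignant Hyperthermia Susceptibility", "count": 0},
    {"row": "CYP2B6", "category": "Poor metabolizer", "count": 497},
    {"row": "CYP2B6", "category": "Intermediate metabolizer", "count": 2284},
    {"row": "CYP2C9", "category": "Intermediate metabolizer", "count": 1832},
    {"row": "CYP2C9", "category": "Poor metabolizer", "count": 99},
    {"row": "CYP2C19", "category": "Rapid metabolizer", "count": 1804},
    {"row": "CYP2C19", "category": "Ultrarapid metabolizer", "count": 395},
    {"row": "CYP2C19", "category": "Poor metabolizer", "count": 113},
    {"row": "CYP2C19", "category": "Intermediate metabolizer", "count": 1197},
    {"row": "CYP2D6", "category": "Poor metabolizer", "count": 114},
    {"row": "CYP2D6", "category": "Ultrarapid metabolizer", "count": 517},
    {"row": "CYP2D6", "category": "Intermediate metabolizer", "count": 1407},
    {"row": "CYP3A5", "category": "Extensive metabolizer (CYP3A5 expressor)", "count": 86},
    {"row": "CYP3A5", "category": "Intermediate metabolizer (CYP3A5 expressor)", "count": 996},
    {"row": "DPYD", "category": "Intermediate metabolizer", "count": 9},
    {"row": "HLA-A*31:01", "category": "Risk of SJS/TEN (Hom)", "count": 10},
    {"row": "HLA-A*31:01", "category": "Risk of SJS/TEN (Het)", "count": 323},
    {"row": "HLA-B*15:02", "category": "Risk of SJS/TEN (Hom)", "count": 0},
    {"row": "HLA-B*15:02", "category": "Risk of SJS/TEN (Het)", "count": 25},
    {"row": "HLA-B*57:01", "category": "Hypersensitivity risk (Hom)", "count": 2},
    {"row": "HLA-B*57:01", "category": "Hypersensitivity risk (Het)", "count": 159},
    {"row": "HLA-B*58:01", "category": "Risk of SCAR (Hom)", "count": 4},
    {"row": "HLA-B*58:01", "category": "Risk of SCAR (Het)", "count": 359},
    {"row": "IFNL3", "category": "Unfavourable response (Hom alt)", "count": 626},
    {"row": "IFNL3", "category": "Unfavourable response (Het)", "count": 2549},
    {"row": "NUDT15", "category": "Intermediate metabolizer", "count": 245},
    {"row": "NUDT15", "category": "Poor metabolizer", "count": 5},
    {"row": "NUDT15", "category": "Indeterminate", "count": 2},
    {"row": "RYR1", "category": "Malignant Hyperthermia Susceptibility", "count": 2},
    {"row": "SLCO1B1", "category": "Decreased function (Increased risk of myopathy)", "count": 1616},
    {"row": "SLCO1B1", "category": "Poor function (High risk of myopathy)", "count": 341},
    {"row": "TPMT", "category": "Intermediate metabolizer", "count": 120},
    {"row": "TPMT", "category": "Poor metabolizer", "count": 1},
    {"row": "VKORC1", "category": "Lower dosage requirement (Hom AA)", "count": 1596},
    {"row": "VKORC1", "category": "Lower dosage requirement (Het GA)", "count": 2799}
  ],
  "totals": {
    "CACNA1S": [0, 0],
    "CYP2B6": [2781, 1295],
    "CYP2C9": [1931, 588],
    "CYP2C19": [3509, 1483],
    "CYP2D6": [2038, 982],
    "CYP3A5": [1082, 1191],
    "DPYD": [9, 10],
    "HLA-A*31:01": [333, 125],
    "HLA-B*15:02": [25, 88],
    "HLA-B*57:01": [161, 151],
    "HLA-B*58:01": [363, 165],
    "IFNL3": [3175, 1353],
    "NUDT15": [252, 185],
    "RYR1": [2, 0],
    "SLCO1B1": [1957, 376],
    "TPMT": [121, 194],
    "VKORC1": [4395, 1230]
  }
}
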