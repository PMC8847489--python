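{
  "version": "pgxpop synthetic cohort preset v1 (reduced panel)",
  "description": "Synthetic per-gene star-allele haplotype frequencies and single-variant / HLA carrier frequencies chosen so that simulated cohorts land near the published Qatari actionable-frequency spectrum. Not observed haplotype frequencies.",
  "star_allele_frequencies": {
    "CYP2B6": {"*1": 0.55, "*2": 0.08, "*4": 0.06, "*22": 0.045, "*6": 0.20, "*9": 0.04, "*18": 0.015, "*36": 0.01},
    "CYP2C9": {"*1": 0.825, "*2": 0.095, "*3": 0.045, "*9": 0.02, "*11": 0.015},
    "CYP2C19": {"*1": 0.65, "*2": 0.12, "*3": 0.02, "*17": 0.18, "*35": 0.03},
    "CYP2D6": {"*1": 0.40, "*2": 0.25, "*4": 0.12, "*10": 0.06, "*17": 0.05, "*41": 0.12},
    "CYP3A5": {"*1": 0.094, "*3": 0.80, "*6": 0.07, "*7": 0.036},
    "DPYD": {"*1": 0.99925, "*2A": 0.0005, "*13": 0.00025},
    "NUDT15": {"*1": 0.979, "*3": 0.019, "*2": 0.002},
    "SLCO1B1": {"*1": 0.822, "*15": 0.10, "*5": 0.04, "*17": 0.028, "*31": 0.01},
    "TPMT": {"*1": 0.99, "*3A": 0.006, "*3C": 0.003, "*2": 0.001}
  },
  "alt_allele_frequencies": {
    "VKORC1": 0.4773,
    "IFNL3": 0.3109,
    "RYR1": 0.000165,
    "CACNA1S": 0.0
  },
  "carrier_frequencies": {
    "HLA-A*31:01": 0.0543,
    "HLA-B*15:02": 0.0041,
    "HLA-B*57:01": 0.0262,
    "HLA-B*58:01": 0.0592
  }
}
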