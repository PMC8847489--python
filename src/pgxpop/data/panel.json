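{
  "version": "pgxpop reduced panel snapshot v1",
  "description": "Frozen, reduced star-allele panel: 15 genes / 17 comparison rows with clinical implementation guidelines. Allele definitions cover a curated subset of defining variants per allele; structural CYP2D6 alleles enter via per-sample overrides.",
  "diplotype_genes": ["CYP2B6", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A5", "DPYD", "NUDT15", "SLCO1B1", "TPMT"],
  "rule_rows": ["VKORC1", "IFNL3", "RYR1", "CACNA1S", "HLA-A*31:01", "HLA-B*15:02", "HLA-B*57:01", "HLA-B*58:01"],
  "actionable_priorities": ["Abnormal/Priority/High Risk"],
  "declared_drug_count": 46,
  "subpopulations": ["PAR", "GAR", "WEP", "AFR", "SAS", "ADM"]
}
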