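{
  "_declared_drug_count": 46,
  "CACNA1S": [
    "desflurane",
    "enflurane",
    "halothane",
    "isoflurane",
    "methoxyflurane",
    "sevoflurane",
    "succinylcholine"
  ],
  "RYR1": [
    "desflurane",
    "enflurane",
    "halothane",
    "isoflurane",
    "methoxyflurane",
    "sevoflurane",
    "succinylcholine"
  ],
  "CYP2B6": [
    "efavirenz"
  ],
  "CYP2C9": [
    "phenytoin",
    "fosphenytoin",
    "celecoxib",
    "flurbiprofen",
    "ibuprofen",
    "meloxicam",
    "piroxicam"
  ],
  "CYP2C19": [
    "clopidogrel",
    "voriconazole",
    "citalopram",
    "escitalopram",
    "sertraline",
    "amitriptyline",
    "imipramine",
    "omeprazole",
    "lansoprazole",
    "pantoprazole"
  ],
  "CYP2D6": [
    "atomoxetine",
    "codeine",
    "ondansetron",
    "tamoxifen",
    "paroxetine",
    "nortriptyline",
    "amitriptyline",
    "imipramine"
  ],
  "CYP3A5": [
    "tacrolimus"
  ],
  "DPYD": [
    "capecitabine",
    "fluorouracil"
  ],
  "HLA-A*31:01": [
    "carbamazepine"
  ],
  "HLA-B*15:02": [
    "carbamazepine",
    "oxcarbazepine",
    "phenytoin",
    "fosphenytoin"
  ],
  "HLA-B*57:01": [
    "abacavir"
  ],
  "HLA-B*58:01": [
    "allopurinol"
  ],
  "IFNL3": [
    "peginterferon alfa-2a",
    "peginterferon alfa-2b",
    "ribavirin"
  ],
  "NUDT15": [
    "azathioprine",
    "mercaptopurine",
    "thioguanine"
  ],
  "TPMT": [
    "azathioprine",
    "mercaptopurine",
    "thioguanine"
  ],
  "SLCO1B1": [
    "simvastatin"
  ],
  "VKORC1": [
    "warfarin"
  ]
}
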