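"""Loaders for the packaged panel snapshot and published summary inputs.

The package ships a frozen, reduced pharmacogene panel (versioned in
``data/panel.json``): allele definition and translation tables for the nine
diplotype-called genes, genotype rules for the single-variant genes and HLA
risk alleles, the gene->drug map, the published cohort-level actionability
counts used as comparison inputs, the IWPC coefficient table, and synthetic
haplotype-frequency presets for the cohort simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .tables import (
    AlleleDefinitionTable,
    GeneDrugMap,
    GenotypeRuleSet,
    TranslationTable,
    load_allele_definitions,
    load_gene_drug_map,
    load_genotype_rules,
    load_translation_table,
)

__all__ = [
    "Panel",
    "data_dir",
    "load_panel",
    "load_published_table",
    "published_row_probabilities",
    "load_frequency_preset",
]

_DATA = Path(__file__).parent / "data"


def data_dir() -> Path:
    return _DATA


@dataclass
class Panel:
    config: dict
    definitions: dict[str, AlleleDefinitionTable]
    translations: dict[str, TranslationTable]
    rules: dict[str, GenotypeRuleSet]
    drug_map: GeneDrugMap

    @property
    def diplotype_genes(self) -> list[str]:
        return list(self.config["diplotype_genes"])

    @property
    def rule_rows(self) -> list[str]:
        return list(self.config["rule_rows"])

    @property
    def rows(self) -> list[str]:
        return sorted(self.diplotype_genes + self.rule_rows)

    def pairs(self) -> list[tuple[AlleleDefinitionTable, TranslationTable]]:
        return [
            (self.definitions[g], self.translations[g]) for g in self.diplotype_genes
        ]


def load_panel(panel_dir: str | Path | None = None) -> Panel:
    """Load the packaged panel (or a compatible panel directory)."""
    base = Path(panel_dir) if panel_dir else _DATA
    config = json.loads((base / "panel.json").read_text())
    pdir = base / "panel"
    definitions, translations = {}, {}
    for gene in config["diplotype_genes"]:
        definitions[gene] = load_allele_definitions(pdir / f"{gene}.definitions.tsv")
        translations[gene] = load_translation_table(pdir / f"{gene}.translation.tsv")
    rules = load_genotype_rules(pdir / "genotype_rules.json")
    drug_map = load_gene_drug_map(pdir / "gene_drugs.json")
    if config.get("declared_drug_count") is not None:
        n = len(drug_map.all_drugs())
        if n != config["declared_drug_count"]:
            raise ValueError(
                f"panel declares {config['declared_drug_count']} drugs, map has {n}"
            )
    return Panel(config, definitions, translations, rules, drug_map)


def load_published_table() -> dict:
    """Published actionability counts: per-category (Qatari) and per-row
    totals (Qatari and 1000 Genomes), with cohort sizes."""
    raw = json.loads((_DATA / "table1_published.json").read_text())
    return {
        "qgp_n": raw["qgp_n"],
        "kg_n": raw["kg_n"],
        "categories": pd.DataFrame(raw["categories"]),
        "totals": raw["totals"],
    }


def published_row_probabilities() -> dict[str, float]:
    """Per-row actionable frequency in the published Qatari cohort."""
    t = load_published_table()
    return {row: counts[0] / t["qgp_n"] for row, counts in t["totals"].items()}


def load_frequency_preset() -> dict:
    return json.loads((_DATA / "qatari_frequencies.json").read_text())
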