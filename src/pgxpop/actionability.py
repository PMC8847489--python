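"""Actionability classification and per-individual burden statistics.

A panel *row* is either a whole gene (diplotype-called or single-variant)
or an HLA risk allele (e.g. ``HLA-B*57:01``); several HLA-B rows belong to
one gene.  A row's phenotype is actionable when its EHR priority is in the
configured actionable set (by default ``Abnormal/Priority/High Risk``).
Burden counts are reported both per row and per distinct gene (HLA-B rows
collapse to one gene for the gene-level count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .caller import DEFAULT_ACTIONABLE_PRIORITIES, UNCERTAIN_PHENOTYPE, DiplotypeCall
from .tables import GeneDrugMap, GenotypeClass, GenotypeRuleSet

__all__ = [
    "PhenotypeAssignment",
    "BurdenRecord",
    "genotype_phenotype",
    "is_actionable",
    "assignments_from_calls",
    "individual_burden",
    "cohort_burden_summary",
    "gene_of_row",
]

NORMAL_PRIORITY = "Normal/Routine/Low Risk"


@dataclass(frozen=True)
class PhenotypeAssignment:
    sample: str
    row: str  # panel row label: gene symbol or HLA allele name
    phenotype: str
    ehr_priority: str
    actionable: bool
    uncertain: bool = False


@dataclass(frozen=True)
class BurdenRecord:
    sample: str
    actionable_gene_count: int
    actionable_row_count: int
    affected_drug_count: int

    @property
    def has_any(self) -> bool:
        return self.actionable_gene_count >= 1


def gene_of_row(row: str) -> str:
    """Collapse an HLA allele row label to its gene symbol."""
    return row.split("*", 1)[0].rstrip() if row.startswith("HLA") else row


def is_actionable(
    phenotype: str,
    ehr_priority: str,
    actionable_priorities: frozenset[str] = DEFAULT_ACTIONABLE_PRIORITIES,
) -> bool:
    """True iff the EHR priority is in the actionable set.

    Uncertain / Indeterminate phenotypes are never actionable regardless of
    any priority string attached to them.
    """
    if phenotype in (UNCERTAIN_PHENOTYPE, "Indeterminate"):
        return False
    return ehr_priority in actionable_priorities


def genotype_phenotype(
    sample: str,
    target: str,
    observed: GenotypeClass,
    rule_set: GenotypeRuleSet,
    actionable_priorities: frozenset[str] = DEFAULT_ACTIONABLE_PRIORITIES,
    row: str | None = None,
) -> PhenotypeAssignment:
    """Apply a single-variant / HLA-carrier rule set to an observed genotype.

    ``target`` is the variant token or HLA allele name the rules key on.
    HOM_REF yields the non-actionable normal assignment; MISSING yields an
    uncertain one; otherwise the most specific matching rule fires
    (HOM_ALT > HET > CARRIER_ANY).
    """
    if not any(r.target == target for r in rule_set.rules):
        raise KeyError(f"no rule for target {target!r} in gene {rule_set.gene}")
    label = row or rule_set.gene
    if observed == GenotypeClass.MISSING:
        return PhenotypeAssignment(sample, label, UNCERTAIN_PHENOTYPE, "", False, True)
    rule = rule_set.match(target, observed)
    if rule is None:
        return PhenotypeAssignment(sample, label, "Normal", NORMAL_PRIORITY, False)
    return PhenotypeAssignment(
        sample,
        label,
        rule.phenotype,
        rule.ehr_priority,
        is_actionable(rule.phenotype, rule.ehr_priority, actionable_priorities),
    )


def assignments_from_calls(calls: list[DiplotypeCall]) -> list[PhenotypeAssignment]:
    """Project diplotype calls into row-level phenotype assignments."""
    return [
        PhenotypeAssignment(
            c.sample, c.gene, c.phenotype, c.ehr_priority, c.actionable, c.uncertain
        )
        for c in calls
    ]


def individual_burden(
    assignments: list[PhenotypeAssignment],
    drug_map: GeneDrugMap,
) -> BurdenRecord:
    """Actionable burden of one sample across the panel.

    Gene count collapses HLA rows to their gene; drug count is the size of
    the union of drugs mapped to actionable rows.
    """
    samples = {a.sample for a in assignments}
    if len(samples) > 1:
        raise ValueError(f"assignments span multiple samples: {sorted(samples)}")
    sample = assignments[0].sample if assignments else ""
    actionable = [a for a in assignments if a.actionable]
    genes = {gene_of_row(a.row) for a in actionable}
    drugs: set[str] = set()
    for a in actionable:
        drugs |= drug_map.drugs_for(a.row)
    return BurdenRecord(sample, len(genes), len(actionable), len(drugs))


def cohort_burden_summary(
    burdens: list[BurdenRecord],
) -> dict[str, float]:
    """Cohort-level burden summary.

    Returns mean actionable genes and rows per individual, mean affected
    drugs, and the percentage of individuals with at least one actionable
    row.
    """
    if not burdens:
        raise ValueError("empty burden list")
    genes = np.array([b.actionable_gene_count for b in burdens], dtype=float)
    rows = np.array([b.actionable_row_count for b in burdens], dtype=float)
    drugs = np.array([b.affected_drug_count for b in burdens], dtype=float)
    return {
        "n": len(burdens),
        "mean_actionable_genes": float(genes.mean()),
        "mean_actionable_rows": float(rows.mean()),
        "mean_affected_drugs": float(drugs.mean()),
        "pct_with_any": float(100.0 * (genes >= 1).mean()),
    }
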