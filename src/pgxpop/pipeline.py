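"""End-to-end orchestration: VCF -> QC -> calls -> statistics -> reports.

Each stage is a pure function of its inputs and the run configuration; the
manifest written alongside the outputs records versions, seeds, thresholds
and the Bonferroni family size, which suffices to reproduce any artifact.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .actionability import (
    assignments_from_calls,
    cohort_burden_summary,
    genotype_phenotype,
    individual_burden,
)
from .caller import call_cohort, load_overrides
from .cohort import filter_variants, read_phased_vcf
from .datasets import Panel, load_panel
from .popstats import actionable_summary, compare_groups, fst, upgma_cluster
from .tables import GenotypeClass, VariantKey
from .warfarin import (
    derive_genetic_covariates,
    dose_category,
    enzyme_inducer_flag,
    iwpc_weekly_dose,
    load_iwpc_coefficients,
    map_race,
    Cyp2c9Category,
    IWPCInput,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    vcf: str
    out_dir: str
    panel_dir: str | None = None
    labels_file: str | None = None  # TSV: sample<TAB>group
    covariates_file: str | None = None
    overrides_file: str | None = None
    hla_carriers_file: str | None = None  # TSV: sample<TAB>row<TAB>genotype
    max_missing: float = 0.01
    hwe_threshold: float = 1e-6
    alpha: float = 0.05
    assume_phased: bool = False
    lenient_missing: bool = False
    denominator: str = "called"
    fst_estimator: str = "hudson"
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha, self.hwe_threshold):
            if not 0 < a < 1:
                raise ValueError(f"alpha/threshold {a} outside (0,1)")


def _read_labels(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _rule_assignments(panel: Panel, cohort, hla_carriers: pd.DataFrame | None):
    """Assignments for single-variant rows and, when supplied, HLA rows."""
    out = []
    for row in panel.rule_rows:
        rule_set = panel.rules[row]
        targets = {r.target for r in rule_set.rules}
        # variant tokens look like chrom:pos:ref:alt[:rsid]; HLA allele
        # names also contain colons but no numeric position field
        variant_targets = [
            t for t in targets if re.match(r"^[^:]+:\d+:[ACGT]+:[ACGT]+(:rs\d+)?$", t)
        ]
        if variant_targets:
            for sample in cohort.samples:
                picked = None
                for t in variant_targets:
                    g = cohort.genotype_class(sample, VariantKey.from_token(t))
                    a = genotype_phenotype(sample, t, g, rule_set, row=row)
                    if picked is None or (a.actionable and not picked.actionable):
                        picked = a
                out.append(picked)
        elif hla_carriers is not None:
            carriers = hla_carriers[hla_carriers["row"] == row]
            status = dict(zip(carriers["sample"], carriers["genotype"]))
            for sample in cohort.samples:
                g = GenotypeClass(status.get(sample, "HOM_REF"))
                out.append(
                    genotype_phenotype(sample, row, g, rule_set, row=row)
                )
    return out


def _warfarin_table(cohort, calls, covariates: pd.DataFrame, panel: Panel):
    coeffs = load_iwpc_coefficients()
    vk_target = next(
        r.target for r in panel.rules["VKORC1"].rules if ":" in r.target
    )
    vk_key = VariantKey.from_token(vk_target)
    c9 = {
        c.sample: c
        for c in calls
        if c.gene == "CYP2C9"
    }
    rows = []
    for rec in covariates.itertuples(index=False):
        sample = rec.sample
        vk_class = (
            cohort.genotype_class(sample, vk_key)
            if sample in cohort.samples
            else GenotypeClass.MISSING
        )
        call = c9.get(sample)
        vk, c9cat = derive_genetic_covariates(
            vk_class,
            call.alleles if call else None,
            call.uncertain if call else True,
        )
        meds = str(rec.meds).split(";") if rec.meds else []
        dose = iwpc_weekly_dose(
            IWPCInput(
                age_decades=rec.age_years / 10.0,
                height_cm=rec.height_cm,
                weight_kg=rec.weight_kg,
                race=map_race(rec.subpopulation),
                enzyme_inducer=enzyme_inducer_flag(meds),
                amiodarone="amiodarone" in [m.strip().lower() for m in meds],
                vkorc1=vk,
                cyp2c9=c9cat,
            ),
            coeffs,
        )
        rows.append(
            {
                "sample": sample,
                "dose_mg_week": round(dose, 4),
                "category": dose_category(dose),
                "vkorc1": vk.value,
                "cyp2c9": c9cat.value,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all stages; returns a map of artifact name -> written path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_panel(config.panel_dir)
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "pgxpop_version": __version__,
        "panel_version": panel.config.get("version"),
        "seed": config.seed,
        "thresholds": {
            "max_missing": config.max_missing,
            "hwe_threshold": config.hwe_threshold,
            "alpha": config.alpha,
        },
        "flags": {
            "assume_phased": config.assume_phased,
            "lenient_missing": config.lenient_missing,
            "denominator": config.denominator,
            "fst_estimator": config.fst_estimator,
        },
    }

    cohort = read_phased_vcf(config.vcf, assume_phased=config.assume_phased)
    cohort, qc = filter_variants(cohort, config.max_missing, config.hwe_threshold)
    qc_path = out / "qc_report.tsv"
    qc.to_csv(qc_path, sep="\t", index=False)
    artifacts["qc_report"] = str(qc_path)

    overrides = load_overrides(config.overrides_file) if config.overrides_file else None
    calls = call_cohort(
        cohort, panel.pairs(), overrides, lenient_missing=config.lenient_missing
    )
    calls_df = pd.DataFrame(
        [
            {
                "sample": c.sample,
                "gene": c.gene,
                "allele1": c.alleles[0],
                "allele2": c.alleles[1],
                "diplotype": c.diplotype,
                "phenotype": c.phenotype,
                "ehr_priority": c.ehr_priority,
                "actionable": c.actionable,
                "uncertain": c.uncertain,
            }
            for c in calls
        ]
    )
    calls_path = out / "diplotype_calls.tsv"
    calls_df.to_csv(calls_path, sep="\t", index=False)
    artifacts["diplotype_calls"] = str(calls_path)

    hla = (
        pd.read_csv(config.hla_carriers_file, sep="\t")
        if config.hla_carriers_file
        else None
    )
    assignments = assignments_from_calls(calls) + _rule_assignments(
        panel, cohort, hla
    )
    assign_df = pd.DataFrame(
        [
            {
                "sample": a.sample,
                "row": a.row,
                "phenotype": a.phenotype,
                "ehr_priority": a.ehr_priority,
                "actionable": a.actionable,
                "uncertain": a.uncertain,
            }
            for a in assignments
        ]
    )
    assign_path = out / "assignments.tsv"
    assign_df.to_csv(assign_path, sep="\t", index=False)
    artifacts["assignments"] = str(assign_path)

    labels = (
        _read_labels(config.labels_file)
        if config.labels_file
        else {s: "ALL" for s in cohort.samples}
    )
    summaries = actionable_summary(assignments, labels, config.denominator)
    summary_path = out / "group_summaries.tsv"
    pd.concat(
        [s.as_frame().assign(group=g) for g, s in summaries.items()]
    ).to_csv(summary_path, sep="\t", index=False)
    artifacts["group_summaries"] = str(summary_path)

    groups = sorted(summaries)
    if len(groups) == 2:
        comparison = compare_groups(
            summaries[groups[0]], summaries[groups[1]], config.alpha
        )
        manifest["bonferroni_family_size"] = sum(
            1 for r in comparison if r.direction != "untestable"
        )
        comp_path = out / "comparison.tsv"
        pd.DataFrame([vars(r) for r in comparison]).to_csv(
            comp_path, sep="\t", index=False
        )
        artifacts["comparison"] = str(comp_path)

    by_sample: dict[str, list] = {}
    for a in assignments:
        by_sample.setdefault(a.sample, []).append(a)
    burdens = [
        individual_burden(rows, panel.drug_map) for rows in by_sample.values()
    ]
    burden_path = out / "burden.tsv"
    pd.DataFrame(
        [
            {
                "sample": b.sample,
                "actionable_genes": b.actionable_gene_count,
                "actionable_rows": b.actionable_row_count,
                "affected_drugs": b.affected_drug_count,
                "has_any": b.has_any,
            }
            for b in burdens
        ]
    ).to_csv(burden_path, sep="\t", index=False)
    artifacts["burden"] = str(burden_path)
    summary = cohort_burden_summary(burdens)
    bs_path = out / "burden_summary.json"
    bs_path.write_text(json.dumps(summary, indent=2))
    artifacts["burden_summary"] = str(bs_path)

    if len(set(labels.values())) >= 2 and cohort.n_variants:
        res = fst(cohort, labels, config.fst_estimator)
        fst_path = out / "fst_pairwise.tsv"
        res.pairwise.to_csv(fst_path, sep="\t")
        artifacts["fst_pairwise"] = str(fst_path)
        manifest["fst_overall"] = res.overall
        tree_path = out / "fst_upgma.nwk"
        tree_path.write_text(upgma_cluster(res.pairwise) + "\n")
        artifacts["fst_tree"] = str(tree_path)

    if config.covariates_file:
        cov = pd.read_csv(config.covariates_file, sep="\t", keep_default_na=False)
        doses = _warfarin_table(cohort, calls, cov, panel)
        dose_path = out / "warfarin_doses.tsv"
        doses.to_csv(dose_path, sep="\t", index=False)
        artifacts["warfarin_doses"] = str(dose_path)

    manifest["artifacts"] = artifacts
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(manifest_path)
    return artifacts
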