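"""Synthetic cohort generation for end-to-end testing without protected data.

The generator emulates the statistical structure the pipeline assumes in
the study cohort (6,045 genomes): known per-gene star-allele haplotype
frequencies, Hardy–Weinberg random pairing of haplotypes, optional
subpopulation differentiation at a target FST via the Balding–Nichols
model, per-genotype missingness, novel-haplotype injection at a decoy
variant, and biobank-like covariates (age 40.2 +/- 12.66 years, 56.7%
women, subpopulation cluster sizes as published).

Everything is deterministic under (config, seed); the emitted truth table
is the oracle for diplotype-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .tables import AlleleDefinitionTable, State, VariantKey

__all__ = [
    "SubpopulationSpec",
    "CovariateSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "sample_diplotypes",
    "truth_to_cohort",
    "emit_phased_vcf",
    "generate_covariates",
    "sample_actionability_bernoulli",
    "default_covariate_spec",
    "default_subpopulations",
]


@dataclass(frozen=True)
class SubpopulationSpec:
    label: str
    size: int
    fst: float  # Balding-Nichols F for this cluster

    def __post_init__(self) -> None:
        if self.size < 0 or not 0 <= self.fst < 1:
            raise ValueError(f"bad subpopulation spec {self}")


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate distributions; defaults mirror the study cohort where
    published (age, sex split) and generic adult anthropometrics where not."""

    age_mean: float = 40.2
    age_sd: float = 12.66
    age_min: float = 18.0
    age_max: float = 90.0
    female_fraction: float = 0.567
    height_mean: float = 165.0
    height_sd: float = 10.0
    weight_mean: float = 78.0
    weight_sd: float = 16.0
    medication_prevalence: dict = field(
        default_factory=lambda: {
            "amiodarone": 0.005,
            "carbamazepine": 0.003,
            "phenytoin": 0.002,
            "rifampicin": 0.001,
        }
    )


def default_subpopulations(fst: float = 0.01) -> list[SubpopulationSpec]:
    """Published QGP cluster sizes (total 6,045), one shared target F."""
    sizes = {"PAR": 1052, "GAR": 2311, "WEP": 1372, "AFR": 92, "SAS": 38, "ADM": 1180}
    return [SubpopulationSpec(k, v, fst) for k, v in sizes.items()]


def default_covariate_spec() -> CovariateSpec:
    return CovariateSpec()


@dataclass
class SimulationConfig:
    gene_frequencies: dict[str, dict[str, float]]  # gene -> star allele -> freq
    n_samples: int = 6045
    seed: int = 0
    missingness: float = 0.0
    novelty_rate: float = 0.0
    subpopulations: list[SubpopulationSpec] | None = None
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    render_any_as: str | None = None  # how to render ANY states ("ref") or error

    def __post_init__(self) -> None:
        for gene, freqs in self.gene_frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{gene}: haplotype frequencies sum to {total}")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{gene}: negative frequency")
        for rate in (self.missingness, self.novelty_rate):
            if not 0 <= rate <= 1:
                raise ValueError(f"rate {rate} outside [0,1]")
        if self.subpopulations is not None:
            total = sum(s.size for s in self.subpopulations)
            if total != self.n_samples:
                raise ValueError(
                    f"subpopulation sizes sum to {total}, n_samples is {self.n_samples}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth: one row per (sample, gene) with the ordered haplotype
    pair as drawn, plus subpopulation labels and covariates."""

    diplotypes: pd.DataFrame  # sample, gene, hap_a, hap_b, subpopulation
    covariates: pd.DataFrame

    def truth_pair(self, sample: str, gene: str) -> tuple[str, str]:
        df = self.diplotypes
        row = df[(df["sample"] == sample) & (df["gene"] == gene)].iloc[0]
        return row["hap_a"], row["hap_b"]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(n)]


def _balding_nichols(
    base: np.ndarray, f: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw subpopulation allele frequencies around ``base`` at target F.

    Dirichlet with concentration p_i (1-F)/F generalizes the biallelic
    Balding-Nichols beta to K haplotypes; F = 0 returns the base exactly.
    """
    if f == 0:
        return base.copy()
    alpha = np.maximum(base * (1 - f) / f, 1e-9)
    return rng.dirichlet(alpha)


def sample_diplotypes(
    config: SimulationConfig,
    tables: dict[str, AlleleDefinitionTable] | None = None,
) -> SyntheticTruth:
    """Draw two haplotypes per (sample, gene) under HWE.

    With subpopulations, each cluster's per-gene frequencies are drawn once
    per run from the Balding-Nichols distribution around the base map.
    When definition tables are supplied, frequency-map alleles must exist
    in them.
    """
    if tables is not None:
        for gene, freqs in config.gene_frequencies.items():
            table = tables.get(gene)
            if table is None:
                raise KeyError(f"no definition table for gene {gene}")
            known = set(table.definitions) | set(table.suballele_map)
            unknown = set(freqs) - known
            if unknown:
                raise KeyError(f"{gene}: frequencies for undefined alleles {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    samples = _sample_ids(config.n_samples)
    if config.subpopulations:
        labels = np.repeat(
            [s.label for s in config.subpopulations],
            [s.size for s in config.subpopulations],
        )
    else:
        labels = np.array(["ALL"] * config.n_samples)

    records = []
    for gene in sorted(config.gene_frequencies):
        freqs = config.gene_frequencies[gene]
        alleles = sorted(freqs)
        base = np.array([freqs[a] for a in alleles], dtype=float)
        pop_freqs: dict[str, np.ndarray] = {}
        if config.subpopulations:
            for spec in config.subpopulations:
                pop_freqs[spec.label] = _balding_nichols(base, spec.fst, rng)
        else:
            pop_freqs["ALL"] = base
        for i, sample in enumerate(samples):
            p = pop_freqs[labels[i]]
            a, b = rng.choice(len(alleles), size=2, p=p)
            records.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "hap_a": alleles[a],
                    "hap_b": alleles[b],
                    "subpopulation": labels[i],
                }
            )
    covariates = generate_covariates(config, labels=labels, rng=rng)
    return SyntheticTruth(pd.DataFrame(records), covariates)


DECOY_SUFFIX = "_decoy"
NOVEL_TRUTH_LABEL = "<novel>"


def _decoy_variant(table: AlleleDefinitionTable) -> VariantKey:
    """A gene-region variant deliberately absent from the definition table."""
    if table.variants:
        v = table.variants[-1]
        return VariantKey(v.chrom, v.pos + 97, "G", "T", None)
    return VariantKey(table.gene + DECOY_SUFFIX, 10_000, "G", "T", None)


def render_haplotype(
    allele: str, table: AlleleDefinitionTable, render_any_as: str | None = None
) -> np.ndarray:
    """State vector of a named allele over the table's variants."""
    name = table.suballele_map.get(allele, allele)
    defn = table.definitions.get(name)
    if defn is None:
        raise KeyError(f"{table.gene}: cannot render undefined allele {allele}")
    vec = defn.copy()
    if (vec == State.ANY).any():
        if render_any_as == "ref":
            vec = np.where(vec == State.ANY, State.REF, vec).astype(np.int8)
        else:
            raise ValueError(
                f"{table.gene} allele {allele} has wildcard positions; set "
                "render_any_as='ref' in the config to render them as reference"
            )
    return vec


def truth_to_cohort(
    truth: SyntheticTruth,
    tables: dict[str, AlleleDefinitionTable],
    config: SimulationConfig,
):
    """Render truth haplotypes into an in-memory phased cohort.

    Novelty injection replaces a haplotype with an all-reference haplotype
    carrying an ALT at the gene's decoy variant (guaranteed NOVEL for any
    strict caller); the truth table is updated to the ``<novel>`` label.
    Missingness knocks out whole genotypes at the configured rate.
    Returns (cohort, possibly novelty-updated truth diplotype table).
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = sorted(tables)
    samples = sorted(truth.diplotypes["sample"].unique())
    n = len(samples)
    sample_idx = {s: i for i, s in enumerate(samples)}

    all_variants: list[VariantKey] = []
    gene_cols: dict[str, tuple[int, int]] = {}
    decoy_col: dict[str, int] = {}
    for gene in genes:
        start = len(all_variants)
        all_variants.extend(tables[gene].variants)
        gene_cols[gene] = (start, len(all_variants))
        if config.novelty_rate > 0:
            decoy_col[gene] = len(all_variants)
            all_variants.append(_decoy_variant(tables[gene]))

    nv = len(all_variants)
    haps = np.zeros((n, nv, 2), dtype=np.int8)
    truth_df = truth.diplotypes.copy()

    for gene in genes:
        table = tables[gene]
        lo, hi = gene_cols[gene]
        sub = truth_df[truth_df["gene"] == gene]
        for idx, row in sub.iterrows():
            i = sample_idx[row["sample"]]
            for hap_no, col in ((0, "hap_a"), (1, "hap_b")):
                if config.novelty_rate > 0 and rng.random() < config.novelty_rate:
                    haps[i, decoy_col[gene], hap_no] = State.ALT
                    truth_df.loc[idx, col] = NOVEL_TRUTH_LABEL
                else:
                    haps[i, lo:hi, hap_no] = render_haplotype(
                        row[col], table, config.render_any_as
                    )
    if config.missingness > 0:
        knockout = rng.random((n, nv)) < config.missingness
        haps[knockout, :] = State.MISSING

    from .cohort import PhasedCohort

    cohort = PhasedCohort(
        samples=samples,
        variants=all_variants,
        haplotypes=haps,
        phased=np.ones((n, nv), dtype=bool),
    )
    return cohort, truth_df


def emit_phased_vcf(
    truth: SyntheticTruth,
    tables: dict[str, AlleleDefinitionTable],
    config: SimulationConfig,
    vcf_path: str,
    truth_path: str | None = None,
) -> pd.DataFrame:
    """Write the rendered cohort as a phased VCFv4.2 file plus truth TSV."""
    from .cohort import write_phased_vcf

    cohort, truth_df = truth_to_cohort(truth, tables, config)
    write_phased_vcf(cohort, vcf_path)
    if truth_path:
        truth_df.to_csv(truth_path, sep="\t", index=False)
    return truth_df


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has ``target_mean``."""
    from scipy.optimize import brentq

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return float(brentq(gap, target_mean - 3 * sd, target_mean + 3 * sd, xtol=1e-9))


def generate_covariates(
    config: SimulationConfig,
    labels: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw biobank-like covariates: truncated-normal age, Bernoulli sex,
    normal height/weight, Bernoulli medication flags."""
    spec = config.covariates
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    n = config.n_samples
    if labels is None:
        if config.subpopulations:
            labels = np.repeat(
                [s.label for s in config.subpopulations],
                [s.size for s in config.subpopulations],
            )
        else:
            labels = np.array(["ALL"] * n)
    # centre the truncated normal so its mean matches the target cohort
    # mean (plain truncation at the adult lower bound would inflate it)
    loc = _truncnorm_loc(spec.age_mean, spec.age_sd, spec.age_min, spec.age_max)
    a = (spec.age_min - loc) / spec.age_sd
    b = (spec.age_max - loc) / spec.age_sd
    age = truncnorm.rvs(a, b, loc=loc, scale=spec.age_sd, size=n, random_state=rng)
    female = rng.random(n) < spec.female_fraction
    height = rng.normal(spec.height_mean, spec.height_sd, size=n)
    weight = np.maximum(rng.normal(spec.weight_mean, spec.weight_sd, size=n), 30.0)
    meds = []
    flags = {
        med: rng.random(n) < prev for med, prev in spec.medication_prevalence.items()
    }
    for i in range(n):
        meds.append(";".join(m for m in sorted(flags) if flags[m][i]))
    return pd.DataFrame(
        {
            "sample": _sample_ids(n),
            "age_years": age,
            "sex": np.where(female, "F", "M"),
            "height_cm": height,
            "weight_kg": weight,
            "subpopulation": labels,
            "meds": meds,
        }
    )


def sample_actionability_bernoulli(
    row_probabilities: dict[str, float],
    n_samples: int,
    seed: int,
) -> pd.DataFrame:
    """Independent per-row Bernoulli actionability per individual.

    A deliberately simple preset for burden statistics: each panel row is
    actionable in an individual with its cohort frequency, independently
    across rows.  Returns a boolean sample x row table.
    """
    rng = np.random.default_rng(seed)
    rows = sorted(row_probabilities)
    probs = np.array([row_probabilities[r] for r in rows])
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("row probabilities must lie in [0,1]")
    draws = rng.random((n_samples, len(rows))) < probs
    return pd.DataFrame(draws, index=_sample_ids(n_samples), columns=rows)
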