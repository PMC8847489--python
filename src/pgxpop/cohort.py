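"""Phased cohort container, VCF I/O and per-variant QC.

Input is a phased multi-sample VCF slice over a pharmacogene region
(biallelic records, ``|``-separated heterozygous genotypes).  QC applies the
standard pre-analysis filters: per-variant missingness and an exact
Hardy–Weinberg equilibrium test, variants failing either are dropped before
star-allele calling or FST estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy.special import gammaln

from .tables import GenotypeClass, State, VariantKey

__all__ = [
    "PhasedCohort",
    "CohortError",
    "parse_region",
    "read_phased_vcf",
    "write_phased_vcf",
    "hwe_exact_test",
    "filter_variants",
]


class CohortError(ValueError):
    """Malformed cohort input or contract violation."""


@dataclass
class PhasedCohort:
    """Haplotype matrix for a set of samples over an ordered variant list.

    ``haplotypes[i, j]`` is the (hapA, hapB) state pair of sample *i* at
    variant *j*; states are ``State.REF``/``ALT``/``MISSING``.  A genotype is
    missing on both haplotypes or on neither.
    """

    samples: list[str]
    variants: list[VariantKey]
    haplotypes: np.ndarray  # (n_samples, n_variants, 2) int8 of State codes
    phased: np.ndarray  # (n_samples, n_variants) bool

    def __post_init__(self) -> None:
        ns, nv = len(self.samples), len(self.variants)
        if self.haplotypes.shape != (ns, nv, 2):
            raise CohortError(
                f"haplotype matrix shape {self.haplotypes.shape} != ({ns}, {nv}, 2)"
            )
        if self.phased.shape != (ns, nv):
            raise CohortError("phased flag matrix shape mismatch")
        a_missing = self.haplotypes[:, :, 0] == State.MISSING
        b_missing = self.haplotypes[:, :, 1] == State.MISSING
        if np.any(a_missing != b_missing):
            raise CohortError("MISSING must affect both haplotypes of a genotype")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError as exc:
            raise CohortError(f"sample {sample!r} not in cohort") from exc

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom_ref, het, hom_alt) counts at variant *j*, missing excluded."""
        g = self.haplotypes[:, j, :]
        called = g[g[:, 0] != State.MISSING]
        alt = (called == State.ALT).sum(axis=1)
        return int((alt == 0).sum()), int((alt == 1).sum()), int((alt == 2).sum())

    def missingness(self, j: int) -> float:
        return float((self.haplotypes[:, j, 0] == State.MISSING).mean())

    def genotype_class(self, sample: str, variant: VariantKey) -> GenotypeClass:
        """Diploid genotype class of one sample at one variant.

        Variants absent from the cohort slice are homozygous reference by
        convention (the slice only carries segregating sites).
        """
        keys = [v.key for v in self.variants]
        if variant.key not in keys:
            return GenotypeClass.HOM_REF
        g = self.haplotypes[self.sample_index(sample), keys.index(variant.key), :]
        if g[0] == State.MISSING:
            return GenotypeClass.MISSING
        n_alt = int((g == State.ALT).sum())
        return (GenotypeClass.HOM_REF, GenotypeClass.HET, GenotypeClass.HOM_ALT)[n_alt]

    def subset_variants(self, keep: np.ndarray) -> "PhasedCohort":
        idx = np.flatnonzero(keep)
        return PhasedCohort(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            haplotypes=self.haplotypes[:, idx, :].copy(),
            phased=self.phased[:, idx].copy(),
        )

    def subset_samples(self, samples: list[str]) -> "PhasedCohort":
        idx = [self.sample_index(s) for s in samples]
        return PhasedCohort(
            samples=list(samples),
            variants=list(self.variants),
            haplotypes=self.haplotypes[idx, :, :].copy(),
            phased=self.phased[idx, :].copy(),
        )


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based, closed)."""
    try:
        chrom, span = region.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
    except ValueError as exc:
        raise CohortError(f"bad region {region!r}, expected chrom:start-end") from exc
    if start < 1 or end < start:
        raise CohortError(f"bad region bounds in {region!r}")
    return chrom, start, end


def read_phased_vcf(
    path: str,
    region: str | None = None,
    assume_phased: bool = False,
) -> PhasedCohort:
    """Decode a phased multi-sample VCF (slice) into a :class:`PhasedCohort`.

    Heterozygous genotypes must be phased (``|``) unless ``assume_phased``;
    ``./.`` becomes MISSING on both haplotypes.  Multi-allelic records must
    be split upstream (``bcftools norm -m-``).
    """
    bounds = parse_region(region) if region else None
    variants: list[VariantKey] = []
    columns: list[list[tuple[int, int, bool]]] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise CohortError(f"{path}: no samples")
        for rec in vcf:
            if bounds is not None:
                chrom, start, end = bounds
                if rec.chrom != chrom or not (start <= rec.pos <= end):
                    continue
            if rec.alts is None or len(rec.alts) != 1:
                raise CohortError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "split with 'bcftools norm -m-' first"
                )
            variants.append(
                VariantKey(rec.chrom, rec.pos, rec.ref, rec.alts[0], rec.id)
            )
            col = []
            for sample in samples:
                call = rec.samples[sample]
                alleles = call.get("GT", (None, None))
                if alleles is None or len(alleles) != 2 or None in alleles:
                    col.append((int(State.MISSING), int(State.MISSING), False))
                    continue
                a, b = alleles
                if a != b and not call.phased and not assume_phased:
                    raise CohortError(
                        f"unphased heterozygote for sample {sample} at "
                        f"{rec.chrom}:{rec.pos}; phase upstream or pass "
                        "assume_phased"
                    )
                col.append((int(bool(a)), int(bool(b)), bool(call.phased)))
            columns.append(col)
    ns, nv = len(samples), len(variants)
    haplotypes = np.full((ns, nv, 2), int(State.MISSING), dtype=np.int8)
    phased = np.zeros((ns, nv), dtype=bool)
    for j, col in enumerate(columns):
        for i, (a, b, ph) in enumerate(col):
            haplotypes[i, j, 0] = a
            haplotypes[i, j, 1] = b
            phased[i, j] = ph
    return PhasedCohort(samples, variants, haplotypes, phased)


def write_phased_vcf(cohort: PhasedCohort, path: str) -> None:
    """Write a cohort back to VCFv4.2, preserving GT fields exactly."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(v.chrom for v in cohort.variants):
        max_pos = max(v.pos for v in cohort.variants if v.chrom == chrom)
        header.add_line(f"##contig=<ID={chrom},length={max_pos + 1000}>")
    for s in cohort.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, v in enumerate(cohort.variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.rsid
            )
            rec.stop = v.pos - 1 + len(v.ref)
            for i, s in enumerate(cohort.samples):
                a, b = cohort.haplotypes[i, j, :]
                if a == State.MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (int(a), int(b))
                    rec.samples[s].phased = bool(cohort.phased[i, j])
            out.write(rec)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and diploid sample size, and
    sums the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed configuration.
    Monomorphic sites return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise CohortError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise CohortError("empty genotype counts")
    rare = n_het + 2 * min(n_hom_ref, n_hom_alt)
    if rare == 0:
        return 1.0
    # log P(het = h | rare allele count, N) up to a shared constant
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    # relative tolerance guards float ties in the <= comparison
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def filter_variants(
    cohort: PhasedCohort,
    max_missing: float = 0.01,
    hwe_threshold: float = 1e-6,
) -> tuple[PhasedCohort, pd.DataFrame]:
    """Apply missingness and HWE filters; return (kept cohort, full report).

    A variant passes iff missingness <= ``max_missing`` and HWE exact
    p >= ``hwe_threshold``.  The report covers every input variant with
    columns ``chrom pos ref alt missingness hwe_p pass reason``.
    """
    if not 0 <= max_missing <= 1:
        raise CohortError(f"max_missing must be in [0,1], got {max_missing}")
    if cohort.n_variants == 0 or cohort.n_samples == 0:
        raise CohortError("empty cohort")
    rows = []
    for j, v in enumerate(cohort.variants):
        miss = cohort.missingness(j)
        counts = cohort.genotype_counts(j)
        hwe_p = hwe_exact_test(*counts) if sum(counts) else 1.0
        reasons = []
        if miss > max_missing:
            reasons.append("missingness")
        if hwe_p < hwe_threshold:
            reasons.append("hwe")
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "missingness": miss,
                "hwe_p": hwe_p,
                "pass": not reasons,
                "reason": ";".join(reasons),
            }
        )
    report = pd.DataFrame(rows)
    kept = cohort.subset_variants(report["pass"].to_numpy())
    return kept, report
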