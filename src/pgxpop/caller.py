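"""Star-allele haplotype matching and diplotype calling.

Each phased haplotype is compared against every named allele in the gene's
definition table.  A definition matches when all of its non-wildcard
positions agree with the haplotype; among matches the most specific allele
wins (most ALT-requiring positions satisfied, then fewest wildcards, then
lexicographic name).  Haplotypes matching no definition are NOVEL, and any
diplotype involving a NOVEL haplotype — or a pair absent from the
translation table — is assigned the Uncertain phenotype and is never
actionable.

MISSING genotypes are handled strictly by default: a MISSING state fails
both REF- and ALT-requiring positions, so partially missing haplotypes can
only match via wildcards and typically surface as NOVEL rather than being
silently imputed.  A lenient mode treats MISSING as REF and is flagged in
the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortError, PhasedCohort
from .tables import (
    AlleleDefinitionTable,
    State,
    TranslationTable,
    collapse_suballele,
    render_diplotype,
    sort_allele_pair,
)

__all__ = [
    "NOVEL",
    "UNCERTAIN_PHENOTYPE",
    "HaplotypeCall",
    "DiplotypeCall",
    "match_haplotype",
    "call_diplotype",
    "call_cohort",
    "load_overrides",
]

NOVEL = "NOVEL"
UNCERTAIN_PHENOTYPE = "Uncertain"
#: EHR priority results treated as clinically actionable
DEFAULT_ACTIONABLE_PRIORITIES = frozenset({"Abnormal/Priority/High Risk"})


@dataclass(frozen=True)
class HaplotypeCall:
    allele_name: str
    matched_nonref_count: int
    observed_states: tuple[int, ...]


@dataclass(frozen=True)
class DiplotypeCall:
    sample: str
    gene: str
    alleles: tuple[str, str]  # sorted, may contain NOVEL
    phenotype: str
    ehr_priority: str
    actionable: bool
    uncertain: bool
    reason: str = ""

    @property
    def diplotype(self) -> str:
        return render_diplotype(*self.alleles)


def match_haplotype(
    hap: np.ndarray,
    table: AlleleDefinitionTable,
    lenient_missing: bool = False,
) -> HaplotypeCall:
    """Match one haplotype state vector against the definition table.

    ``hap`` holds ``State`` codes (REF/ALT/MISSING) over ``table.variants``.
    Returns the most specific matching allele or the NOVEL sentinel.
    """
    hap = np.asarray(hap, dtype=np.int8)
    if hap.shape != (len(table.variants),):
        raise CohortError(
            f"haplotype length {hap.shape} != {len(table.variants)} table variants"
        )
    if lenient_missing:
        hap = np.where(hap == State.MISSING, State.REF, hap)
    best: tuple[int, int, str] | None = None
    for name, defn in table.definitions.items():
        fixed = defn != State.ANY
        if not np.array_equal(defn[fixed], hap[fixed]):
            continue
        nonref = int((defn == State.ALT).sum())
        n_any = int((~fixed).sum())
        key = (-nonref, n_any, name)
        if best is None or key < best:
            best = key
    if best is None:
        return HaplotypeCall(NOVEL, 0, tuple(int(s) for s in hap))
    return HaplotypeCall(best[2], -best[0], tuple(int(s) for s in hap))


def _sample_haplotypes(
    sample: str, cohort: PhasedCohort, table: AlleleDefinitionTable
) -> tuple[np.ndarray, np.ndarray, tuple[bool, bool]]:
    """Project a sample's two haplotypes onto the table's variant order.

    Table positions absent from the cohort slice are reference; cohort
    positions outside the table are ignored for matching, but an ALT
    carried at such a position (on a chromosome the table covers) is
    reported per haplotype so callers can optionally treat it as evidence
    of an uncatalogued haplotype.
    """
    i = cohort.sample_index(sample)
    col_of = {v.key: j for j, v in enumerate(cohort.variants)}
    chroms = {v.chrom for v in table.variants}
    n = len(table.variants)
    hap_a = np.full(n, int(State.REF), dtype=np.int8)
    hap_b = np.full(n, int(State.REF), dtype=np.int8)
    for k, v in enumerate(table.variants):
        j = col_of.get(v.key)
        if j is not None:
            hap_a[k] = cohort.haplotypes[i, j, 0]
            hap_b[k] = cohort.haplotypes[i, j, 1]
    table_keys = {v.key for v in table.variants}
    off_a = off_b = False
    for j, v in enumerate(cohort.variants):
        if v.chrom in chroms and v.key not in table_keys:
            off_a = off_a or cohort.haplotypes[i, j, 0] == State.ALT
            off_b = off_b or cohort.haplotypes[i, j, 1] == State.ALT
    return hap_a, hap_b, (off_a, off_b)


def _classify_pair(
    gene: str,
    sample: str,
    allele_a: str,
    allele_b: str,
    translation: TranslationTable,
    actionable_priorities: frozenset[str] = DEFAULT_ACTIONABLE_PRIORITIES,
    reason: str = "",
) -> DiplotypeCall:
    pair = sort_allele_pair(allele_a, allele_b)
    if NOVEL in pair:
        return DiplotypeCall(
            sample, gene, pair, UNCERTAIN_PHENOTYPE, "", False, True,
            reason or "novel_haplotype",
        )
    hit = translation.lookup(*pair)
    if hit is None:
        return DiplotypeCall(
            sample, gene, pair, UNCERTAIN_PHENOTYPE, "", False, True,
            reason or "unlisted_diplotype",
        )
    phenotype, priority = hit
    return DiplotypeCall(
        sample, gene, pair, phenotype, priority,
        priority in actionable_priorities, False, reason,
    )


def call_diplotype(
    sample: str,
    gene_cohort: PhasedCohort,
    table: AlleleDefinitionTable,
    translation: TranslationTable,
    lenient_missing: bool = False,
    actionable_priorities: frozenset[str] = DEFAULT_ACTIONABLE_PRIORITIES,
    offtable_alt_is_novel: bool = False,
) -> DiplotypeCall:
    """Call one sample's diplotype for one gene from its phased haplotypes.

    By default unlisted positions in the gene slice are ignored (unlisted =
    reference, the definition-table convention).  With
    ``offtable_alt_is_novel`` a haplotype carrying an ALT at a gene-region
    position absent from the table is called NOVEL: the observed variant
    combination is not catalogued, so no star allele can be asserted.
    """
    hap_a, hap_b, offtable = _sample_haplotypes(sample, gene_cohort, table)
    call_a = match_haplotype(hap_a, table, lenient_missing)
    call_b = match_haplotype(hap_b, table, lenient_missing)
    names = [call_a.allele_name, call_b.allele_name]
    if offtable_alt_is_novel:
        names = [NOVEL if off else n for n, off in zip(names, offtable)]
    a, b = (
        collapse_suballele(n, table) if n != NOVEL else NOVEL for n in names
    )
    return _classify_pair(
        table.gene, sample, a, b, translation, actionable_priorities
    )


def call_cohort(
    cohort: PhasedCohort,
    panel: list[tuple[AlleleDefinitionTable, TranslationTable]],
    overrides: dict[tuple[str, str], tuple[str, str]] | None = None,
    lenient_missing: bool = False,
    actionable_priorities: frozenset[str] = DEFAULT_ACTIONABLE_PRIORITIES,
    offtable_alt_is_novel: bool = False,
) -> list[DiplotypeCall]:
    """One diplotype call per (sample, gene), ordered by sample then gene.

    ``overrides`` maps (sample, gene) to a pre-called allele pair — used for
    genes whose alleles cannot be derived from SNV haplotypes (structural
    CYP2D6 alleles called by a dedicated caller) — and takes precedence over
    haplotype matching.  Genes whose region has no variant overlap with the
    cohort still get calls (all-reference haplotypes project onto the table).
    """
    if not panel:
        raise CohortError("empty panel")
    overrides = overrides or {}
    calls: list[DiplotypeCall] = []
    for sample in cohort.samples:
        for table, translation in sorted(panel, key=lambda p: p[0].gene):
            key = (sample, table.gene)
            if key in overrides:
                a, b = overrides[key]
                a = collapse_suballele(a, table)
                b = collapse_suballele(b, table)
                calls.append(
                    _classify_pair(
                        table.gene, sample, a, b, translation,
                        actionable_priorities, reason="override",
                    )
                )
            else:
                calls.append(
                    call_diplotype(
                        sample, cohort, table, translation,
                        lenient_missing, actionable_priorities,
                        offtable_alt_is_novel,
                    )
                )
    return calls


def load_overrides(path: str) -> dict[tuple[str, str], tuple[str, str]]:
    """Read a per-sample override TSV: ``sample gene allele1 allele2``."""
    out: dict[tuple[str, str], tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["sample", "gene", "allele1", "allele2"]:
            raise CohortError(f"{path}: bad override header {header}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, gene, a, b = line.rstrip("\n").split("\t")[:4]
            out[(sample, gene)] = (a, b)
    return out
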