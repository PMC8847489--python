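"""Population-level statistics over actionability assignments and genotypes.

Covers four stages of the population analysis:

* per-group actionable frequency tables (counts and percentages per panel
  row), with either called-only or whole-group denominators;
* pooled two-proportion z-tests between two groups with Bonferroni
  adjustment over the testable rows;
* pharmacogene FST between subpopulations (Hudson and Weir–Cockerham 1984
  estimators, per-variant components combined as a ratio of sums);
* UPGMA clustering of the pairwise FST matrix into a newick dendrogram.

Extreme tail probabilities are carried in log10 space so that contrasts
with p ~ 1e-96 survive into reports without underflow.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .actionability import PhenotypeAssignment
from .cohort import CohortError, PhasedCohort
from .tables import State

__all__ = [
    "PopulationSummary",
    "ComparisonRow",
    "ZResult",
    "FstResult",
    "actionable_summary",
    "summary_from_category_counts",
    "category_counts",
    "two_proportion_z",
    "compare_groups",
    "fst",
    "upgma_cluster",
]

_LN10 = math.log(10.0)


def _pct(count: int, n: int) -> float:
    """Percentage rounded half-up to 2 decimal places."""
    if n == 0:
        return 0.0
    return math.floor(100.0 * count / n * 100 + 0.5) / 100


@dataclass
class PopulationSummary:
    """Per-row actionable counts for one group of samples."""

    group: str
    rows: list[tuple[str, int, int]]  # (row label, actionable count, denominator)

    def __post_init__(self) -> None:
        for label, count, n in self.rows:
            if not 0 <= count <= max(n, 0):
                raise ValueError(f"{label}: count {count} outside [0, {n}]")

    @property
    def labels(self) -> list[str]:
        return [r[0] for r in self.rows]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"row": label, "count": c, "n": n, "pct": _pct(c, n)}
                for label, c, n in self.rows
            ]
        )

    def row(self, label: str) -> tuple[int, int, float]:
        for lab, c, n in self.rows:
            if lab == label:
                return c, n, _pct(c, n)
        raise KeyError(label)


@dataclass(frozen=True)
class ZResult:
    z: float
    p: float
    log10_p: float
    testable: bool


@dataclass(frozen=True)
class ComparisonRow:
    row: str
    count_a: int
    n_a: int
    pct_a: float
    count_b: int
    n_b: int
    pct_b: float
    z: float
    log10_p_raw: float
    log10_p_adj: float
    significant: bool
    direction: str  # higher / lower / equal / untestable

    @property
    def p_raw(self) -> float:
        return 10.0 ** self.log10_p_raw if math.isfinite(self.log10_p_raw) else math.nan

    @property
    def p_adj(self) -> float:
        return 10.0 ** self.log10_p_adj if math.isfinite(self.log10_p_adj) else math.nan


def actionable_summary(
    assignments: list[PhenotypeAssignment],
    group_labels: dict[str, str],
    denominator: str = "called",
) -> dict[str, PopulationSummary]:
    """Per-group, per-row actionable counts.

    ``denominator='called'`` excludes uncertain assignments from both the
    numerator and the denominator; ``'all'`` keeps every sample of the group
    in the denominator.  Every sample must be labelled.
    """
    if denominator not in ("called", "all"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    for a in assignments:
        if a.sample not in group_labels:
            raise KeyError(f"sample {a.sample!r} has no group label")
    groups = sorted(set(group_labels.values()))
    rows = sorted({a.row for a in assignments})
    out: dict[str, PopulationSummary] = {}
    for g in groups:
        stats = []
        for row in rows:
            sub = [
                a
                for a in assignments
                if a.row == row and group_labels[a.sample] == g
            ]
            count = sum(a.actionable for a in sub)
            n = len(sub) if denominator == "all" else sum(not a.uncertain for a in sub)
            stats.append((row, count, n))
        out[g] = PopulationSummary(g, stats)
    return out


def category_counts(
    assignments: list[PhenotypeAssignment],
    group_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-(group, row, phenotype) counts — the per-metabolizer breakdown."""
    records = [
        {
            "group": group_labels[a.sample] if group_labels else "all",
            "row": a.row,
            "phenotype": a.phenotype,
            "actionable": a.actionable,
        }
        for a in assignments
    ]
    df = pd.DataFrame(records)
    return (
        df.groupby(["group", "row", "phenotype", "actionable"])
        .size()
        .reset_index(name="count")
        .sort_values(["group", "row", "phenotype"], ignore_index=True)
    )


def summary_from_category_counts(
    categories: pd.DataFrame,
    n: int,
    group: str = "summary",
) -> PopulationSummary:
    """Aggregate pre-summarized per-category counts into per-row totals.

    ``categories`` needs columns ``row``, ``count`` (one record per
    actionable phenotype category, as published summary tables print them);
    the per-row actionable count is their sum.  Rows absent from the input
    are not invented; a row whose categories sum to zero is kept at zero.
    """
    agg = categories.groupby("row")["count"].sum()
    return PopulationSummary(group, [(row, int(c), n) for row, c in agg.items()])


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> ZResult:
    """Two-sided pooled two-proportion z-test without continuity correction.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (x1 + x2)/(n1 + n2); p = 2 Phi(-|z|).  Contrasts with no events
    (or all events) in both groups pooled are untestable.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie in [0, n]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZResult(math.nan, math.nan, math.nan, testable=False)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    log10_p = (math.log(2.0) + norm.logsf(abs(z))) / _LN10
    return ZResult(z, min(1.0, 2.0 * norm.sf(abs(z))), log10_p, testable=True)


def compare_groups(
    a: PopulationSummary,
    b: PopulationSummary,
    alpha: float = 0.05,
) -> list[ComparisonRow]:
    """Row-wise z-tests between two groups, Bonferroni-adjusted.

    The Bonferroni family is the set of testable rows of this comparison;
    untestable rows (no events in either group) are reported but carry no
    p-value and are never significant.
    """
    if a.labels != b.labels:
        raise ValueError("summaries have different row labels")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    results = [
        (label, a.row(label), b.row(label), two_proportion_z(a.row(label)[0], a.row(label)[1], b.row(label)[0], b.row(label)[1]))
        for label in a.labels
    ]
    m = sum(r.testable for *_, r in results)
    out = []
    log10_m = math.log10(m) if m else 0.0
    for label, (ca, na, pa), (cb, nb, pb), zres in results:
        if not zres.testable:
            out.append(
                ComparisonRow(
                    label, ca, na, pa, cb, nb, pb,
                    math.nan, math.nan, math.nan, False, "untestable",
                )
            )
            continue
        log10_adj = min(0.0, zres.log10_p + log10_m)
        significant = log10_adj < math.log10(alpha)
        direction = "higher" if pa > pb else ("lower" if pa < pb else "equal")
        out.append(
            ComparisonRow(
                label, ca, na, pa, cb, nb, pb,
                zres.z, zres.log10_p, log10_adj, significant, direction,
            )
        )
    return out


@dataclass
class FstResult:
    estimator: str
    groups: list[str]
    overall: float
    pairwise: pd.DataFrame  # symmetric, zero diagonal (clamped at 0)
    per_variant: pd.DataFrame = field(repr=False, default=None)

    def pair(self, a: str, b: str) -> float:
        return float(self.pairwise.loc[a, b])


def _group_counts(cohort: PhasedCohort, samples_by_group: dict[str, list[str]]):
    """Per-group per-variant (n_diploid called, alt allele count, het count)."""
    out = {}
    for g, samples in samples_by_group.items():
        idx = [cohort.sample_index(s) for s in samples]
        haps = cohort.haplotypes[idx, :, :]  # (ng, nv, 2)
        called = haps[:, :, 0] != State.MISSING
        alt = (haps == State.ALT).sum(axis=2)  # per sample per variant
        het = (alt == 1) & called
        out[g] = (
            called.sum(axis=0).astype(float),
            np.where(called, alt, 0).sum(axis=0).astype(float),
            het.sum(axis=0).astype(float),
        )
    return out


def _hudson_components(counts, g1: str, g2: str) -> tuple[np.ndarray, np.ndarray]:
    n1, alt1, _ = counts[g1]
    n2, alt2, _ = counts[g2]
    c1, c2 = 2 * n1, 2 * n2  # allele counts
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = alt1 / c1, alt2 / c2
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(c1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(c2 - 1, 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = (c1 > 1) & (c2 > 1) & np.isfinite(num) & np.isfinite(den)
    return np.where(ok, num, 0.0), np.where(ok, den, 0.0)


def _wc_components(counts, groups: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) theta components a and a+b+c per variant."""
    r = len(groups)
    n = np.stack([counts[g][0] for g in groups])  # (r, nv) diploid counts
    alt = np.stack([counts[g][1] for g in groups])
    het = np.stack([counts[g][2] for g in groups])
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2 * n)
        h = het / n
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        total = a + b + c
    ok = (n > 1).all(axis=0) & np.isfinite(a) & np.isfinite(total)
    return np.where(ok, a, 0.0), np.where(ok, total, 0.0)


def fst(
    cohort: PhasedCohort,
    group_labels: dict[str, str],
    estimator: str = "hudson",
) -> FstResult:
    """Fixation index between subpopulations, ratio-of-sums over variants.

    ``estimator='hudson'`` (default, the Plink 2.0 convention) or
    ``'weir_cockerham'``.  The pairwise matrix comes from two-group runs;
    with more than two groups the overall estimate pools component sums
    across all unordered pairs (Hudson) or uses the full multi-population
    estimator (Weir–Cockerham).  Reported values are clamped at 0.
    """
    if estimator not in ("hudson", "weir_cockerham"):
        raise ValueError(f"unknown estimator {estimator!r}")
    samples_by_group: dict[str, list[str]] = {}
    for s in cohort.samples:
        if s not in group_labels:
            raise CohortError(f"sample {s!r} has no subpopulation label")
        samples_by_group.setdefault(group_labels[s], []).append(s)
    groups = sorted(samples_by_group)
    if len(groups) < 2:
        raise CohortError("FST needs at least two groups")
    counts = _group_counts(cohort, samples_by_group)
    for g in groups:
        if counts[g][0].sum() == 0:
            raise CohortError(f"group {g!r} has no called genotypes")

    def pair_components(g1, g2):
        if estimator == "hudson":
            return _hudson_components(counts, g1, g2)
        return _wc_components(counts, [g1, g2])

    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    pair_sums = []
    for g1, g2 in itertools.combinations(groups, 2):
        num, den = pair_components(g1, g2)
        ns, ds = num.sum(), den.sum()
        val = ns / ds if ds > 0 else 0.0
        mat.loc[g1, g2] = mat.loc[g2, g1] = max(0.0, val)
        pair_sums.append((ns, ds))

    if estimator == "weir_cockerham":
        num, den = _wc_components(counts, groups)
        overall = num.sum() / den.sum() if den.sum() > 0 else 0.0
        per_variant = pd.DataFrame({"numerator": num, "denominator": den})
    elif len(groups) == 2:
        num, den = pair_components(groups[0], groups[1])
        overall = num.sum() / den.sum() if den.sum() > 0 else 0.0
        per_variant = pd.DataFrame({"numerator": num, "denominator": den})
    else:
        ns = sum(x for x, _ in pair_sums)
        ds = sum(x for _, x in pair_sums)
        overall = ns / ds if ds > 0 else 0.0
        per_variant = None
    return FstResult(estimator, groups, float(overall), mat, per_variant)


def upgma_cluster(distance: pd.DataFrame) -> str:
    """UPGMA agglomeration of a distance matrix into a newick string.

    Ties break on the lexicographically smallest merged leaf set, so output
    is deterministic.  Branch lengths place each leaf at depth equal to half
    its cophenetic distance from any leaf it merges with (ultrametric tree).
    """
    labels = list(distance.index)
    if list(distance.columns) != labels:
        raise ValueError("distance matrix index and columns differ")
    d = distance.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")

    # cluster state: id -> (sorted leaf names, size, height, newick fragment)
    clusters: dict[int, tuple[tuple[str, ...], int, float, str]] = {
        i: ((lab,), 1, 0.0, lab) for i, lab in enumerate(labels)
    }
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): d[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted(clusters[i][0][0] for i in kv[0])),
            ),
        )
        (pair, dmin) = best
        i, j = sorted(pair, key=lambda k: clusters[k][0])
        leaves_i, size_i, h_i, nwk_i = clusters[i]
        leaves_j, size_j, h_j, nwk_j = clusters[j]
        height = dmin / 2.0
        nwk = f"({nwk_i}:{height - h_i:.10g},{nwk_j}:{height - h_j:.10g})"
        merged = (
            tuple(sorted(leaves_i + leaves_j)),
            size_i + size_j,
            height,
            nwk,
        )
        del clusters[i], clusters[j]
        for pair_key in [k for k in dist if i in k or j in k]:
            del dist[pair_key]
        # UPGMA distance to the new cluster = unweighted mean over all
        # original leaf pairs (matrices here are tiny: one row per group)
        idx_of = {lab: k for k, lab in enumerate(labels)}
        for k, (leaves_k, *_rest) in clusters.items():
            vals = [d[idx_of[x], idx_of[y]] for x in merged[0] for y in leaves_k]
            dist[frozenset((next_id, k))] = float(np.mean(vals))
        clusters[next_id] = merged
        next_id += 1
    (_, _, _, nwk) = next(iter(clusters.values()))
    return nwk + ";"
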