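"""Frequency summaries, two-proportion z-tests, FST estimators and UPGMA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxpop.actionability import PhenotypeAssignment
from pgxpop.cohort import PhasedCohort
from pgxpop.popstats import (
    PopulationSummary,
    actionable_summary,
    compare_groups,
    fst,
    summary_from_category_counts,
    two_proportion_z,
    upgma_cluster,
)
from pgxpop.tables import State, VariantKey

ACT = "Abnormal/Priority/High Risk"
NORM = "Normal/Routine/Low Risk"


# --- summaries -----------------------------------------------------------

def _assign(sample, row, actionable, uncertain=False):
    ph = "Uncertain" if uncertain else ("Poor" if actionable else "Normal")
    return PhenotypeAssignment(
        sample, row, ph, "" if uncertain else (ACT if actionable else NORM),
        actionable, uncertain,
    )


def test_actionable_summary_counts_and_denominators():
    assignments = [
        _assign("S0", "G1", True),
        _assign("S1", "G1", False),
        _assign("S2", "G1", False, uncertain=True),
    ]
    labels = {"S0": "A", "S1": "A", "S2": "A"}
    called = actionable_summary(assignments, labels, denominator="called")["A"]
    assert called.row("G1") == (1, 2, 50.0)
    everyone = actionable_summary(assignments, labels, denominator="all")["A"]
    assert everyone.row("G1") == (1, 3, 33.33)


def test_actionable_summary_requires_labels():
    with pytest.raises(KeyError):
        actionable_summary([_assign("S0", "G1", True)], {})


def test_summary_aggregation_identity():
    """Combined-group actionable count equals the sum over constituents."""
    assignments = [
        _assign(f"S{i}", "G1", i % 3 == 0) for i in range(30)
    ]
    split = {f"S{i}": ("X" if i < 18 else "Y") for i in range(30)}
    combined = {f"S{i}": "ALL" for i in range(30)}
    by_group = actionable_summary(assignments, split)
    total = actionable_summary(assignments, combined)["ALL"]
    assert total.row("G1")[0] == (
        by_group["X"].row("G1")[0] + by_group["Y"].row("G1")[0]
    )


def test_category_aggregation_reproduces_published_percentages(panel):
    """Summing the published per-category counts reproduces the printed
    combined per-gene actionable percentages at 2 decimal places."""
    from pgxpop.datasets import load_published_table

    t = load_published_table()
    summary = summary_from_category_counts(t["categories"], t["qgp_n"])
    assert summary.row("CYP2C19")[2] == 58.05
    assert summary.row("SLCO1B1")[2] == 32.37
    assert summary.row("VKORC1")[0] == 4395


# --- z-test --------------------------------------------------------------

def test_z_identical_proportions():
    r = two_proportion_z(10, 100, 10, 100)
    assert r.z == 0.0 and r.p == 1.0


def test_z_matches_direct_formula():
    x1, n1, x2, n2 = 1957, 6045, 376, 2504
    r = two_proportion_z(x1, n1, x2, n2)
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    assert r.z == pytest.approx(z, rel=1e-12)
    assert r.z == pytest.approx(16.4, abs=0.05)


def test_z_untestable_when_no_events():
    assert not two_proportion_z(0, 50, 0, 80).testable
    assert not two_proportion_z(50, 50, 80, 80).testable


@settings(max_examples=200, deadline=None)
@given(
    st.integers(0, 500), st.integers(1, 500),
    st.integers(0, 500), st.integers(1, 500),
)
def test_z_antisymmetry(x1, n1, x2, n2):
    x1, x2 = min(x1, n1), min(x2, n2)
    a = two_proportion_z(x1, n1, x2, n2)
    b = two_proportion_z(x2, n2, x1, n1)
    if not a.testable:
        assert not b.testable
        return
    assert a.z == pytest.approx(-b.z, rel=1e-12, abs=1e-12)
    assert a.p == pytest.approx(b.p, rel=1e-12)


def test_compare_groups_bonferroni_and_directions():
    a = PopulationSummary("A", [("g1", 30, 100), ("g2", 10, 100), ("g3", 0, 100)])
    b = PopulationSummary("B", [("g1", 5, 100), ("g2", 12, 100), ("g3", 0, 100)])
    rows = compare_groups(a, b, alpha=0.05)
    by = {r.row: r for r in rows}
    assert by["g3"].direction == "untestable" and not by["g3"].significant
    # Bonferroni family = 2 testable rows
    testable = [r for r in rows if r.direction != "untestable"]
    for r in testable:
        assert r.p_adj == pytest.approx(min(1.0, 2 * r.p_raw), rel=1e-9)
    assert by["g1"].direction == "higher"
    assert by["g2"].direction == "lower"


def test_compare_summary_with_itself_nothing_significant():
    a = PopulationSummary("A", [("g1", 30, 100), ("g2", 10, 100)])
    rows = compare_groups(a, a)
    assert not any(r.significant for r in rows)
    assert all(r.direction in ("equal", "untestable") for r in rows)


def test_adjusted_p_monotone_and_bounded():
    a = PopulationSummary("A", [(f"g{i}", 10 + i, 100) for i in range(8)])
    b = PopulationSummary("B", [(f"g{i}", 10, 100) for i in range(8)])
    rows = [r for r in compare_groups(a, b) if r.direction != "untestable"]
    ordered = sorted(rows, key=lambda r: r.log10_p_raw)
    adj = [r.log10_p_adj for r in ordered]
    assert all(x <= y + 1e-12 for x, y in zip(adj, adj[1:]))  # monotone (ties ok)
    assert all(r.p_adj <= 1.0 + 1e-12 for r in rows)


# --- FST -----------------------------------------------------------------

def _two_group_cohort(geno_a, geno_b):
    """One-variant cohort; genotypes given as ALT-allele dosages per sample."""
    doses = list(geno_a) + list(geno_b)
    n = len(doses)
    haps = np.zeros((n, 1, 2), dtype=np.int8)
    for i, dmg in enumerate(doses):
        haps[i, 0, 0] = State.ALT if dmg >= 1 else State.REF
        haps[i, 0, 1] = State.ALT if dmg == 2 else State.REF
    cohort = PhasedCohort(
        samples=[f"S{i}" for i in range(n)],
        variants=[VariantKey("1", 100, "A", "G")],
        haplotypes=haps,
        phased=np.ones((n, 1), dtype=bool),
    )
    labels = {f"S{i}": ("P1" if i < len(geno_a) else "P2") for i in range(n)}
    return cohort, labels


def test_hudson_matches_one_variant_closed_form():
    # group 1: 4 samples with 3 ALT alleles of 8; group 2: 4 with 6 of 8
    cohort, labels = _two_group_cohort([2, 1, 0, 0], [2, 2, 1, 1])
    res = fst(cohort, labels, estimator="hudson")
    p1, p2, c1, c2 = 3 / 8, 6 / 8, 8, 8
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (c1 - 1) - p2 * (1 - p2) / (c2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    assert res.overall == pytest.approx(num / den, rel=1e-12)
    assert res.pair("P1", "P2") == pytest.approx(max(0.0, num / den), rel=1e-12)


@pytest.mark.parametrize("estimator", ["hudson", "weir_cockerham"])
def test_fixed_difference_gives_fst_one(estimator):
    cohort, labels = _two_group_cohort([0, 0, 0, 0], [2, 2, 2, 2])
    res = fst(cohort, labels, estimator=estimator)
    assert res.overall == pytest.approx(1.0, abs=1e-9)


def test_identical_groups_give_fst_near_zero():
    rng = np.random.default_rng(3)
    doses = rng.binomial(2, 0.4, size=400)
    cohort, labels = _two_group_cohort(doses[:200], doses[200:])
    res = fst(cohort, labels)
    assert abs(res.overall) < 0.05
    assert res.pair("P1", "P2") >= 0.0  # reported matrix clamped


def test_fst_pairwise_matrix_symmetric_zero_diagonal():
    cohort, labels = _two_group_cohort([2, 1, 0, 1], [2, 2, 0, 1])
    res = fst(cohort, labels)
    m = res.pairwise
    assert np.allclose(m.to_numpy(), m.to_numpy().T)
    assert np.all(np.diag(m.to_numpy()) == 0)


# --- UPGMA ---------------------------------------------------------------

def _dm(labels, entries):
    df = pd.DataFrame(0.0, index=labels, columns=labels)
    for (a, b), v in entries.items():
        df.loc[a, b] = df.loc[b, a] = v
    return df


def test_upgma_two_leaves():
    nwk = upgma_cluster(_dm(["A", "B"], {("A", "B"): 0.08}))
    assert nwk == "(A:0.04,B:0.04);"


def test_upgma_nearest_pair_merges_first():
    nwk = upgma_cluster(
        _dm(["A", "B", "C"], {("A", "B"): 0.01, ("A", "C"): 0.1, ("B", "C"): 0.1})
    )
    assert nwk.startswith("((A:0.005,B:0.005)")


def test_upgma_four_leaf_hand_trace():
    """Classic hand-traced example: merge (A,B) at 2, then (C,D) at 4, then
    the two clusters at mean of the four cross distances."""
    d = _dm(
        ["A", "B", "C", "D"],
        {
            ("A", "B"): 2.0,
            ("A", "C"): 6.0,
            ("A", "D"): 10.0,
            ("B", "C"): 6.0,
            ("B", "D"): 10.0,
            ("C", "D"): 4.0,
        },
    )
    nwk = upgma_cluster(d)
    # heights: (A,B) at 1; (C,D) at 2; root at (6+10+6+10)/4/2 = 4
    assert nwk == "((A:1,B:1):3,(C:2,D:2):2);"
    # cross-check against scipy average-linkage cophenetic distances
    from scipy.cluster.hierarchy import average, cophenet
    from scipy.spatial.distance import squareform

    Z = average(squareform(d.to_numpy()))
    coph = squareform(cophenet(Z))
    assert coph[0, 1] == pytest.approx(2.0)
    assert coph[2, 3] == pytest.approx(4.0)
    assert coph[0, 2] == pytest.approx(8.0)


def test_upgma_rejects_asymmetric_input():
    d = _dm(["A", "B"], {("A", "B"): 0.1})
    d.iloc[0, 1] = 0.2
    with pytest.raises(ValueError, match="symmetric"):
        upgma_cluster(d)
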