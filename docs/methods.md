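# Methods

This note documents the models and procedures `pgxpop` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not demonstrate about real data.

## Star-allele matching

An allele definition table assigns each named star allele a state vector
over the gene's defining variants: REF, ALT or ANY (wildcard). A phased
haplotype (states REF/ALT/MISSING per variant) *matches* a definition when
every non-wildcard position agrees. Among matching definitions the call is
the most specific one:

1. most ALT-requiring positions satisfied,
2. then fewest wildcard positions,
3. then lexicographically smallest allele name.

The reference allele (all-REF, conventionally `*1`) is the call for an
all-reference haplotype; a haplotype matching no definition is `NOVEL`.
The tie-break order is a package convention chosen to make calls
reproducible: definition tables in the wild overlap (an allele defined on a
subset of another's positions matches whenever the superset does), and the
most-specific-wins rule mirrors the translation-table convention that
unlisted positions are reference.

**MISSING policy.** Strict by default: a MISSING state fails both REF- and
ALT-requiring positions (only wildcards tolerate it), so partially missing
haplotypes surface as NOVEL/uncertain rather than being imputed to
reference. A `lenient_missing` mode treats MISSING as REF; outputs from
that mode carry the flag in the run manifest.

**Off-table variants.** Positions in the gene slice that no definition
uses are ignored by default (unlisted = reference, the definition-table
convention). An opt-in mode (`offtable_alt_is_novel`) instead calls a
haplotype NOVEL when it carries an ALT at such a position: the observed
variant combination is then not catalogued, so no star allele can honestly
be asserted. The synthetic generator's novelty injection uses exactly this
mechanism (see below).

**Suballeles and structural alleles.** Suballeles (`*2.001`) collapse to
their core allele before translation. Copy-number and hybrid alleles
(`*2×2`, `*68 + *4`) cannot be derived from SNV haplotypes; they enter via
a per-sample override file of pre-called allele pairs and pass through to
translation lookup as opaque labels.

**Diplotypes.** The unordered pair of (collapsed) haplotype calls is looked
up in the gene's translation table, yielding a phenotype and an EHR
priority. Actionable ⇔ priority ∈ {`Abnormal/Priority/High Risk`}
(configurable). Any pair containing NOVEL, and any pair absent from the
table, is `Uncertain` — and Uncertain is never actionable.

## QC filters

Per variant: missingness (fraction of genotypes with `./.`) and a
two-sided exact Hardy–Weinberg test. The HWE test conditions on the
observed allele counts and diploid sample size and sums the probabilities
of all heterozygote counts whose conditional probability does not exceed
the observed configuration's; monomorphic sites score 1. Defaults:
missingness ≤ 0.01 (the conventional cohort threshold for this analysis),
HWE p ≥ 1e-6 (a common WGS QC convention; the exact-test choice and its
alpha are package decisions — chi-square alternatives behave similarly away
from small counts but poorly near them). HWE is computed on the whole
cohort, not per subpopulation.

## Population statistics

**Summaries.** Per group and panel row, the actionable count and
percentage (rounded half-up to 2 d.p.). Two denominator modes: `called`
(uncertain calls excluded from numerator and denominator, the default) and
`all` (whole group in the denominator). Published per-gene denominators
drift by a few samples around the cohort size, so neither mode is asserted
as "the" published convention; both are available.

**Two-proportion z-test.** Pooled variance, two-sided, no continuity
correction: z = (p̂₁−p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)), p = 2Φ(−|z|). Rows with no
events (or all events) pooled are untestable and excluded from the
Bonferroni family, which is the set of testable rows of the comparison
actually performed (16 for the packaged 17-row panel contrast); the family
size is logged in the run manifest. Tail probabilities are carried in
log10 space so contrasts around p ~ 1e-96 survive into reports without
underflowing to zero.

**F<sub>ST</sub>.** Two estimators, both as ratios of per-variant component
sums (never means of ratios): Hudson (default, the convention of current
cohort tooling) with numerator (p̂₁−p̂₂)² − p̂₁(1−p̂₁)/(n₁−1) − p̂₂(1−p̂₂)/(n₂−1)
and denominator p̂₁(1−p̂₂)+p̂₂(1−p̂₁) over allele counts, and Weir–Cockerham
(1984) θ for two or more populations. Pairwise matrices come from
two-group runs and are clamped at 0 for reporting; the unclamped overall
estimate is preserved (small negative values are information about
near-zero differentiation).

**UPGMA.** Implemented directly (matrices here have one row per
subpopulation) so that ties break deterministically on the
lexicographically smallest merged leaf set and the output is a newick
string with ultrametric branch lengths (leaf depth = half the cophenetic
distance). The agglomeration is cross-checked against SciPy
average-linkage cophenetic distances in the tests; the in-package
implementation exists for the deterministic tie-break and newick
rendering, not because the linkage algorithm is novel.

## Warfarin dosing

The IWPC pharmacogenetic regression predicts √(weekly dose in mg):

    √dose = β₀ + β_age·(age/10) + β_h·height_cm + β_w·weight_kg
            + race term + VKORC1 term + CYP2C9 term
            + enzyme-inducer term + amiodarone term

The published coefficient table is transcribed into
`data/iwpc_coefficients.json` (version-tagged); the logic embeds no
numbers, so the config file is the single source of truth. Covariate
conventions: age consumed in decades; subpopulation→race mapping SAS→Asian,
AFR→Black or African American, all other clusters→Missing or Mixed;
enzyme inducer ⇔ any of carbamazepine, phenytoin, rifampin, rifampicin in
the medication list; CYP2C9 diplotypes outside the *1/*2/*3 covariate set
(e.g. *1/*11) and uncertain calls map to the Unknown category, as do
missing VKORC1 genotypes. Weekly-dose categories are inclusive at both
bounds: LOW ≤ 21 mg, HIGH ≥ 49 mg.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes in
its source cohort:

- **Haplotype sampling.** Two haplotypes per (sample, gene) drawn
  independently from the gene's star-allele frequency map — i.e.
  Hardy–Weinberg pairing. Packaged presets give each gene a frequency
  spectrum that lands simulated actionable-diplotype frequencies near the
  published cohort spectrum; they are constructed presets, not observed
  haplotype frequencies.
- **Subpopulations.** Cluster labels and sizes default to the published
  six-cluster composition (total 6,045). Differentiation uses the
  Balding–Nichols model: per cluster and gene, allele frequencies are drawn
  once per run from a Dirichlet with concentration p·(1−F)/F around the
  base frequencies (the K-allele generalisation of the biallelic beta);
  F = 0 reproduces the base exactly, and pairwise Hudson F<sub>ST</sub>
  between two clusters simulated at parameter F estimates F.
- **Noise.** Missingness knocks out whole genotypes at a configured rate.
  Novelty injection replaces a haplotype with an all-reference haplotype
  carrying an ALT at a *decoy* variant — a gene-region position present in
  the emitted VCF but absent from every definition table — which the
  caller's uncatalogued-variant mode deterministically calls NOVEL.
  Alleles with wildcard positions need a concrete rendering choice
  (`render_any_as="ref"`) before they can be written to VCF.
- **Covariates.** Age from a normal truncated to [18, 90] whose location is
  solved so the *truncated* mean equals the published cohort mean
  (40.2 y, SD 12.66) — plain truncation at the adult lower bound would
  inflate the mean by about a year. Sex Bernoulli(0.567 female). Height
  and weight are generic adult normals (165 ± 10 cm, 78 ± 16 kg): the
  source cohort's anthropometrics are not published, so these are
  explicitly non-cohort defaults. Medication flags are Bernoulli with
  small default prevalences (amiodarone 0.5%, inducers ≲ 0.3%), again
  package defaults rather than cohort values.
- **Burden preset.** For burden statistics only, a deliberately simple
  preset draws per-row actionability as independent Bernoulli variables at
  the published per-row frequencies. Under independence the expected mean
  rows per individual is the sum of row frequencies (≈ 3.66) and the
  expected fraction with ≥ 1 actionable row is 1−∏(1−pᵢ) (≈ 99.4%) —
  close to, and a useful check against, the published per-individual
  figures, but not a model of between-gene correlation.

What passing tests on synthetic cohorts therefore show: the caller inverts
the generator exactly in the noise-free case, degrades to
NOVEL/uncertain — never to a silent wrong call — under injected noise, and
the estimators recover known generator parameters. What they do not show:
robustness to real-data phenomena the generator omits — within-gene LD
beyond haplotype structure, genotyping error correlated with sequence
context, population-specific rare suballeles, or structural-variant
complexity (structural alleles are override inputs here, never called).

## Numerical choices and degenerate inputs

- Exact HWE probabilities via log-gamma accumulation, normalised within
  each configuration set; the ≤ comparison uses a 1e-12 relative guard for
  float ties. The tests check equality against exact rational enumeration
  for every configuration up to 50 diploids.
- Percentages round half-up (not banker's) to match printed summary
  conventions.
- Untestable contrasts (no events pooled) propagate as NaN z/p with an
  `untestable` direction rather than raising mid-table.
- F<sub>ST</sub> variants with undefined components (a group with < 2
  called alleles) contribute zero to both sums.
- The two-sample z at identical proportions returns exactly (0, 1).
- Empty cohorts, unlabelled samples, asymmetric distance matrices and
  negative doses raise immediately with named errors.

## Test problem sizes

Suite defaults: exhaustive HWE oracle to N = 50 diploids; diplotype
recovery at 5,000 samples × 3 genes plus novelty at 2,500 samples;
F<sub>ST</sub> recovery over 20 seeds × 40 loci × 300 samples per target F;
burden at the full published cohort size (6,045). These sizes give the
Monte-Carlo assertions comfortable 3-SE margins while keeping the default
suite fast.

## Known limitations

- The packaged panel is a reduced frozen snapshot: a curated subset of
  defining variants and alleles per gene with CPIC-style function/activity
  phenotype maps. It is internally consistent and version-stamped, but it
  is not a verbatim copy of any external release; analyses of real cohorts
  should swap in a current curated panel directory.
- UGT1A1 is excluded from the panel (not callable with confidence from
  short-read data); HLA typing and structural-variant calling are input
  interfaces, not computations.
- Unphased heterozygotes are an error by design (`--assume-phased` exists
  for pre-phased data mislabelled by upstream tools); no EM-style
  statistical phasing is attempted.
- All panel genes are autosomal; haploid/X handling is out of scope.
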