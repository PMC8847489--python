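"""Panel data model: allele definition tables, diplotype->phenotype translation
tables, single-variant genotype rules and gene->drug maps.

An *allele definition table* maps named star alleles (e.g. ``CYP2C19*17``,
written ``*17``) to the allele state required at each of the gene's defining
variant positions.  States are ``REF`` (reference base required), ``ALT``
(alternate base required) or ``ANY`` (wildcard: the position does not
discriminate this allele).  The reference allele (conventionally ``*1``) is
all-REF.  Suballeles (``*2.001``) collapse to their core allele (``*2``)
before any phenotype lookup.

File dialects (tab separated, ``#`` comment lines ignored):

* definition table: first column ``allele``, optional second column ``core``
  (non-empty marks the row as a suballele of that core allele), then one
  column per variant headed ``chrom:pos:ref:alt[:rsid]``; cells ``0`` = REF,
  ``1`` = ALT, ``.`` = ANY.
* translation table: columns ``allele1 allele2 phenotype ehr_priority``;
  lookup is symmetric in the unordered allele pair.
* genotype rules: JSON list of rules keyed by variant or HLA allele name.
* gene->drug map: JSON object mapping a panel row label to a drug list.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "State",
    "VariantKey",
    "AlleleDefinitionTable",
    "TranslationTable",
    "GenotypeRule",
    "GenotypeRuleSet",
    "GeneDrugMap",
    "PanelError",
    "load_allele_definitions",
    "write_allele_definitions",
    "load_translation_table",
    "load_genotype_rules",
    "load_gene_drug_map",
    "collapse_suballele",
    "sort_allele_pair",
    "render_diplotype",
]

_RSID_RE = re.compile(r"^rs\d+$")


class PanelError(ValueError):
    """Malformed panel file or violated table invariant."""


class State(enum.IntEnum):
    """Allele state at one variant position.

    ``REF``/``ALT`` appear in both definitions and observed haplotypes;
    ``ANY`` only in definitions; ``MISSING`` only in observed haplotypes.
    """

    REF = 0
    ALT = 1
    ANY = 2
    MISSING = 3


_STATE_TOKENS = {"0": State.REF, "1": State.ALT, ".": State.ANY}
_TOKEN_OF_STATE = {State.REF: "0", State.ALT: "1", State.ANY: "."}


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic variant identified by VCF-style coordinates (1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise PanelError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise PanelError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.rsid is not None and not _RSID_RE.match(self.rsid):
            raise PanelError(f"malformed rsID {self.rsid!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for matching: rsID is annotation only."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def header_token(self) -> str:
        base = f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"
        return f"{base}:{self.rsid}" if self.rsid else base

    @classmethod
    def from_token(cls, token: str) -> "VariantKey":
        parts = token.split(":")
        if len(parts) not in (4, 5):
            raise PanelError(f"bad variant column header {token!r}")
        chrom, pos, ref, alt = parts[:4]
        rsid = parts[4] if len(parts) == 5 else None
        try:
            position = int(pos)
        except ValueError as exc:
            raise PanelError(f"non-integer position in {token!r}") from exc
        return cls(chrom, position, ref, alt, rsid)


def _star_sort_key(name: str) -> tuple[int, float, str]:
    """Sort star alleles by numeric index (*2 before *10), then text.

    Opaque labels (structural alleles like ``*68 + *4``, HLA names) sort
    after simple star alleles, lexicographically.
    """
    m = re.match(r"^\*(\d+(?:\.\d+)?)$", name)
    if m:
        return (0, float(m.group(1)), name)
    return (1, 0.0, name)


def sort_allele_pair(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b), key=_star_sort_key))  # type: ignore[return-value]


def render_diplotype(a: str, b: str) -> str:
    """Canonical unordered rendering, e.g. ``*1/*17``."""
    x, y = sort_allele_pair(a, b)
    return f"{x}/{y}"


@dataclass
class AlleleDefinitionTable:
    gene: str
    reference_allele_name: str
    variants: list[VariantKey]
    definitions: dict[str, np.ndarray]  # allele -> int8 vector of State codes
    suballele_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.variants)
        for name, vec in self.definitions.items():
            if len(vec) != n:
                raise PanelError(
                    f"{self.gene} allele {name}: {len(vec)} states for {n} variants"
                )
        ref = self.definitions.get(self.reference_allele_name)
        if ref is None:
            raise PanelError(
                f"{self.gene}: reference allele {self.reference_allele_name} undefined"
            )
        if n and not np.all(ref == State.REF):
            raise PanelError(
                f"{self.gene}: reference allele {self.reference_allele_name} is not all-REF"
            )
        seen: dict[bytes, str] = {}
        for name, vec in self.definitions.items():
            sig = vec.tobytes()
            if sig in seen:
                raise PanelError(
                    f"{self.gene}: alleles {seen[sig]} and {name} have identical definitions"
                )
            seen[sig] = name
        for sub, core in self.suballele_map.items():
            if core not in self.definitions:
                raise PanelError(
                    f"{self.gene}: suballele {sub} maps to undefined core allele {core}"
                )

    @property
    def allele_names(self) -> list[str]:
        return sorted(self.definitions, key=_star_sort_key)


@dataclass
class TranslationTable:
    """Diplotype -> (phenotype, EHR priority) lookup, symmetric in the pair."""

    gene: str
    entries: dict[tuple[str, str], tuple[str, str]]

    def lookup(self, a: str, b: str) -> tuple[str, str] | None:
        return self.entries.get(sort_allele_pair(a, b))


class GenotypeClass(enum.Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    CARRIER_ANY = "CARRIER_ANY"  # rule-side only: fires on HET or HOM_ALT
    MISSING = "MISSING"


@dataclass(frozen=True)
class GenotypeRule:
    target: str  # variant token (chrom:pos:ref:alt[:rsid]) or HLA allele name
    genotype: GenotypeClass
    phenotype: str
    ehr_priority: str


@dataclass
class GenotypeRuleSet:
    gene: str
    rules: list[GenotypeRule]

    def match(self, target: str, observed: GenotypeClass) -> GenotypeRule | None:
        """Most specific rule firing for an observed genotype.

        Precedence HOM_ALT > HET > CARRIER_ANY; at most one rule fires.
        """
        if observed in (GenotypeClass.HOM_REF, GenotypeClass.MISSING):
            return None
        candidates = [r for r in self.rules if r.target == target]
        for wanted in (observed, GenotypeClass.CARRIER_ANY):
            for rule in candidates:
                if rule.genotype == wanted:
                    return rule
        return None


@dataclass
class GeneDrugMap:
    drugs: dict[str, list[str]]  # panel row label -> drug names
    declared_drug_count: int | None = None

    def __post_init__(self) -> None:
        if self.declared_drug_count is not None:
            n = len(self.all_drugs())
            if n != self.declared_drug_count:
                raise PanelError(
                    f"drug map declares {self.declared_drug_count} drugs but lists {n}"
                )

    def all_drugs(self) -> set[str]:
        return {d for ds in self.drugs.values() for d in ds}

    def drugs_for(self, row: str) -> set[str]:
        return set(self.drugs.get(row, ()))


def _read_tsv_rows(path: str | Path) -> list[list[str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.rstrip("\n").split("\t"))
    if not rows:
        raise PanelError(f"{path}: empty table")
    return rows


def load_allele_definitions(path: str | Path) -> AlleleDefinitionTable:
    """Read an allele definition table (dialect in the module docstring).

    The gene symbol and reference allele come from ``#gene=`` / ``#ref=``
    header comments; the reference defaults to ``*1``.
    """
    text = Path(path).read_text()
    gene, ref_name = None, "*1"
    for line in text.splitlines():
        if line.startswith("#gene="):
            gene = line.split("=", 1)[1].strip()
        elif line.startswith("#ref="):
            ref_name = line.split("=", 1)[1].strip()
    if gene is None:
        raise PanelError(f"{path}: missing '#gene=' header")
    rows = _read_tsv_rows(path)
    header = rows[0]
    if not header or header[0] != "allele":
        raise PanelError(f"{path}: first column must be 'allele'")
    has_core = len(header) > 1 and header[1] == "core"
    first_variant_col = 2 if has_core else 1
    variants = [VariantKey.from_token(tok) for tok in header[first_variant_col:]]
    if len({v.key for v in variants}) != len(variants):
        raise PanelError(f"{path}: duplicate variant columns")

    definitions: dict[str, np.ndarray] = {}
    suballele_map: dict[str, str] = {}
    for row in rows[1:]:
        name = row[0]
        if name in definitions or name in suballele_map:
            raise PanelError(f"{path}: duplicate allele name {name}")
        core = row[1].strip() if has_core and len(row) > 1 else ""
        if core:
            suballele_map[name] = core
            continue
        cells = row[first_variant_col:]
        if len(cells) != len(variants):
            raise PanelError(
                f"{path}: allele {name} has {len(cells)} states for "
                f"{len(variants)} variant columns"
            )
        try:
            vec = np.array([_STATE_TOKENS[c] for c in cells], dtype=np.int8)
        except KeyError as exc:
            raise PanelError(f"{path}: allele {name}: bad state token {exc}") from exc
        definitions[name] = vec
    return AlleleDefinitionTable(gene, ref_name, variants, definitions, suballele_map)


def write_allele_definitions(table: AlleleDefinitionTable, path: str | Path) -> None:
    lines = [f"#gene={table.gene}", f"#ref={table.reference_allele_name}"]
    header = ["allele", "core"] + [v.header_token() for v in table.variants]
    lines.append("\t".join(header))
    for name in table.allele_names:
        vec = table.definitions[name]
        lines.append(
            "\t".join([name, ""] + [_TOKEN_OF_STATE[State(s)] for s in vec])
        )
    for sub in sorted(table.suballele_map, key=_star_sort_key):
        core = table.suballele_map[sub]
        lines.append("\t".join([sub, core] + [""] * len(table.variants)))
    Path(path).write_text("\n".join(lines) + "\n")


def load_translation_table(path: str | Path) -> TranslationTable:
    """Read a diplotype->phenotype translation table.

    Rows stating different phenotypes or priorities for the same unordered
    pair are a format error; exact duplicates are tolerated.
    """
    rows = _read_tsv_rows(path)
    header = rows[0]
    expected = ["allele1", "allele2", "phenotype", "ehr_priority"]
    if header[: len(expected)] != expected:
        raise PanelError(f"{path}: header must be {expected}")
    gene = Path(path).stem.replace(".translation", "")
    entries: dict[tuple[str, str], tuple[str, str]] = {}
    for row in rows[1:]:
        if len(row) < 4:
            raise PanelError(f"{path}: short row {row!r}")
        a, b, phenotype, priority = row[:4]
        if not phenotype or not priority:
            raise PanelError(f"{path}: empty phenotype/priority for {a}/{b}")
        pair = sort_allele_pair(a, b)
        value = (phenotype, priority)
        if pair in entries and entries[pair] != value:
            raise PanelError(
                f"{path}: conflicting entries for {pair[0]}/{pair[1]}: "
                f"{entries[pair]} vs {value}"
            )
        entries[pair] = value
    return TranslationTable(gene, entries)


def load_genotype_rules(path: str | Path) -> dict[str, GenotypeRuleSet]:
    """Read single-variant / HLA-carrier genotype rules from JSON."""
    raw = json.loads(Path(path).read_text())
    out: dict[str, GenotypeRuleSet] = {}
    for gene, rules in raw.items():
        parsed = [
            GenotypeRule(
                target=r["target"],
                genotype=GenotypeClass(r["genotype"]),
                phenotype=r["phenotype"],
                ehr_priority=r["ehr_priority"],
            )
            for r in rules
        ]
        out[gene] = GenotypeRuleSet(gene, parsed)
    return out


def load_gene_drug_map(path: str | Path) -> GeneDrugMap:
    raw = json.loads(Path(path).read_text())
    declared = raw.pop("_declared_drug_count", None)
    return GeneDrugMap(drugs=raw, declared_drug_count=declared)


def collapse_suballele(name: str, table: AlleleDefinitionTable) -> str:
    """Map a suballele (``*2.001``) to its core allele (``*2``).

    Names without a map entry — core alleles, structural labels like
    ``*68 + *4``, the NOVEL sentinel — pass through unchanged.
    """
    if not name:
        raise PanelError("empty allele name")
    return table.suballele_map.get(name, name)
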