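"""IWPC pharmacogenetic warfarin dose prediction.

The IWPC regression predicts the square root of the weekly maintenance dose
(mg/week) from age, height, weight, race category, enzyme-inducer and
amiodarone co-medication, the VKORC1 -1639G>A (rs9923231) genotype and the
CYP2C9 diplotype (restricted to the *1/*2/*3 covariate set).  The published
coefficient table ships as a versioned JSON config; the logic here never
embeds numeric coefficients.

Cohort subpopulation labels map onto the IWPC race categories as follows:
South Asian -> Asian, African -> Black or African American, all other
clusters -> Missing or Mixed race.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .tables import GenotypeClass

__all__ = [
    "Race",
    "Vkorc1Genotype",
    "Cyp2c9Category",
    "IWPCInput",
    "IWPCCoefficients",
    "load_iwpc_coefficients",
    "map_race",
    "derive_genetic_covariates",
    "iwpc_weekly_dose",
    "dose_category",
    "LOW_DOSE_MAX",
    "HIGH_DOSE_MIN",
]

#: weekly-dose category bounds in mg/week, both inclusive
LOW_DOSE_MAX = 21.0
HIGH_DOSE_MIN = 49.0


class Race(enum.Enum):
    ASIAN = "Asian"
    BLACK_AFRICAN_AMERICAN = "Black or African American"
    MISSING_OR_MIXED = "Missing or Mixed race"


class Vkorc1Genotype(enum.Enum):
    GG = "G/G"
    GA = "A/G"
    AA = "A/A"
    UNKNOWN = "Unknown"


class Cyp2c9Category(enum.Enum):
    S1_1 = "*1/*1"
    S1_2 = "*1/*2"
    S1_3 = "*1/*3"
    S2_2 = "*2/*2"
    S2_3 = "*2/*3"
    S3_3 = "*3/*3"
    UNKNOWN = "Unknown"


#: QGP subpopulation cluster -> IWPC race category
_SUBPOP_RACE = {
    "PAR": Race.MISSING_OR_MIXED,
    "GAR": Race.MISSING_OR_MIXED,
    "WEP": Race.MISSING_OR_MIXED,
    "ADM": Race.MISSING_OR_MIXED,
    "AFR": Race.BLACK_AFRICAN_AMERICAN,
    "SAS": Race.ASIAN,
}


@dataclass(frozen=True)
class IWPCInput:
    age_decades: float
    height_cm: float
    weight_kg: float
    race: Race
    enzyme_inducer: bool
    amiodarone: bool
    vkorc1: Vkorc1Genotype
    cyp2c9: Cyp2c9Category

    def __post_init__(self) -> None:
        if self.age_decades <= 0:
            raise ValueError(f"age_decades must be positive, got {self.age_decades}")
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")


@dataclass(frozen=True)
class IWPCCoefficients:
    """Regression terms on the sqrt(weekly mg) scale, keyed by term name."""

    version: str
    terms: dict

    _REQUIRED = (
        "intercept",
        "age_decades",
        "height_cm",
        "weight_kg",
        "vkorc1_GA",
        "vkorc1_AA",
        "vkorc1_unknown",
        "cyp2c9_1_2",
        "cyp2c9_1_3",
        "cyp2c9_2_2",
        "cyp2c9_2_3",
        "cyp2c9_3_3",
        "cyp2c9_unknown",
        "race_asian",
        "race_black_african_american",
        "race_missing_or_mixed",
        "enzyme_inducer",
        "amiodarone",
    )

    def __post_init__(self) -> None:
        missing = [t for t in self._REQUIRED if t not in self.terms]
        if missing:
            raise ValueError(f"coefficient table is missing terms: {missing}")


def load_iwpc_coefficients(path: str | Path | None = None) -> IWPCCoefficients:
    """Load the coefficient table (packaged default when no path given)."""
    if path is None:
        raw = json.loads(
            resources.files("pgxpop.data").joinpath("iwpc_coefficients.json").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    return IWPCCoefficients(version=raw["version"], terms=raw["terms"])


def map_race(subpopulation: str) -> Race:
    try:
        return _SUBPOP_RACE[subpopulation]
    except KeyError as exc:
        raise KeyError(
            f"unknown subpopulation label {subpopulation!r}; "
            f"expected one of {sorted(_SUBPOP_RACE)}"
        ) from exc


_CYP2C9_DIRECT = {
    ("*1", "*1"): Cyp2c9Category.S1_1,
    ("*1", "*2"): Cyp2c9Category.S1_2,
    ("*1", "*3"): Cyp2c9Category.S1_3,
    ("*2", "*2"): Cyp2c9Category.S2_2,
    ("*2", "*3"): Cyp2c9Category.S2_3,
    ("*3", "*3"): Cyp2c9Category.S3_3,
}


def derive_genetic_covariates(
    vkorc1_genotype: GenotypeClass,
    cyp2c9_alleles: tuple[str, str] | None,
    cyp2c9_uncertain: bool = False,
) -> tuple[Vkorc1Genotype, Cyp2c9Category]:
    """Map raw calls onto the IWPC genetic covariate categories.

    CYP2C9 diplotypes involving any allele outside *1/*2/*3 (for example
    *11, clinically relevant but not an IWPC term) and uncertain calls fall
    into the Unknown category, as do missing VKORC1 genotypes.
    """
    vk = {
        GenotypeClass.HOM_REF: Vkorc1Genotype.GG,
        GenotypeClass.HET: Vkorc1Genotype.GA,
        GenotypeClass.HOM_ALT: Vkorc1Genotype.AA,
    }.get(vkorc1_genotype, Vkorc1Genotype.UNKNOWN)
    if cyp2c9_alleles is None or cyp2c9_uncertain:
        return vk, Cyp2c9Category.UNKNOWN
    pair = tuple(sorted(cyp2c9_alleles))
    return vk, _CYP2C9_DIRECT.get(pair, Cyp2c9Category.UNKNOWN)


_VK_TERM = {
    Vkorc1Genotype.GG: None,
    Vkorc1Genotype.GA: "vkorc1_GA",
    Vkorc1Genotype.AA: "vkorc1_AA",
    Vkorc1Genotype.UNKNOWN: "vkorc1_unknown",
}
_C9_TERM = {
    Cyp2c9Category.S1_1: None,
    Cyp2c9Category.S1_2: "cyp2c9_1_2",
    Cyp2c9Category.S1_3: "cyp2c9_1_3",
    Cyp2c9Category.S2_2: "cyp2c9_2_2",
    Cyp2c9Category.S2_3: "cyp2c9_2_3",
    Cyp2c9Category.S3_3: "cyp2c9_3_3",
    Cyp2c9Category.UNKNOWN: "cyp2c9_unknown",
}
_RACE_TERM = {
    Race.ASIAN: "race_asian",
    Race.BLACK_AFRICAN_AMERICAN: "race_black_african_american",
    Race.MISSING_OR_MIXED: "race_missing_or_mixed",
}


def iwpc_weekly_dose(inp: IWPCInput, coeffs: IWPCCoefficients) -> float:
    """Predicted weekly warfarin dose in mg: (linear predictor)^2."""
    t = coeffs.terms
    lp = (
        t["intercept"]
        + t["age_decades"] * inp.age_decades
        + t["height_cm"] * inp.height_cm
        + t["weight_kg"] * inp.weight_kg
        + t[_RACE_TERM[inp.race]]
        + (t["enzyme_inducer"] if inp.enzyme_inducer else 0.0)
        + (t["amiodarone"] if inp.amiodarone else 0.0)
    )
    for term in (_VK_TERM[inp.vkorc1], _C9_TERM[inp.cyp2c9]):
        if term is not None:
            lp += t[term]
    return lp * lp


def dose_category(dose: float) -> str:
    """LOW (<= 21 mg/week), HIGH (>= 49 mg/week) or INTERMEDIATE."""
    if dose < 0:
        raise ValueError(f"negative dose {dose}")
    if dose <= LOW_DOSE_MAX:
        return "LOW"
    if dose >= HIGH_DOSE_MIN:
        return "HIGH"
    return "INTERMEDIATE"


#: medications counted as enzyme inducers for the IWPC inducer flag
ENZYME_INDUCERS = frozenset({"carbamazepine", "phenytoin", "rifampin", "rifampicin"})


def enzyme_inducer_flag(medications: list[str]) -> bool:
    return any(m.strip().lower() in ENZYME_INDUCERS for m in medications)
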