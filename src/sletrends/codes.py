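"""Code lists and drug metadata used across the pipeline.

Everything here is configuration, not logic: ICD-10 codes defining SLE,
the departments that count as SLE-diagnosing specialists, ATC codes for
the analysed drug classes, and the glucocorticoid prednisolone-equivalence
table (potency factor and WHO DDD in mg per substance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: ICD-10 codes defining an SLE-coded visit.
SLE_ICD10: tuple[str, ...] = ("M32.1", "M32.8", "M32.9")

#: Departments that typically diagnose SLE ("specialist" visits).
SPECIALIST_DEPARTMENTS: tuple[str, ...] = (
    "rheumatology",
    "dermatology",
    "nephrology",
    "internal medicine",
    "paediatrics",
)

#: Calendar cohorts: diagnosis-period label -> (first year, last year), inclusive.
COHORT_PERIODS: dict[str, tuple[int, int]] = {
    "2005-2008": (2005, 2008),
    "2009-2012": (2009, 2012),
    "2013-2016": (2013, 2016),
    "2017-2021": (2017, 2021),
}

#: Oral systemic glucocorticoids (ATC H02AB).
GC_ATC: dict[str, str] = {
    "H02AB01": "betamethasone",
    "H02AB02": "dexamethasone",
    "H02AB04": "methylprednisolone",
    "H02AB06": "prednisolone",
    "H02AB07": "prednisone",
    "H02AB09": "hydrocortisone",
    "H02AB10": "cortisone",
}

HCQ_ATC = "P01BA02"

#: Immunosuppressants analysed, ATC -> class label.
IS_ATC: dict[str, str] = {
    "L04AX01": "IS:AZA",
    "L04AX03": "IS:MTX",
    "L04AA06": "IS:MMF",
    "L01AA01": "IS:CYC",
    "L04AA13": "IS:LEF",
    "L04AD02": "IS:TAC",
    "L04AD01": "IS:CSA",
}

#: Default ATC -> drug-class map used by the exposure engine.
ATC_CLASSES: dict[str, str] = (
    {atc: "GC" for atc in GC_ATC} | {HCQ_ATC: "HCQ"} | dict(IS_ATC)
)

IS_CLASSES: tuple[str, ...] = tuple(sorted(set(IS_ATC.values())))

#: The eight mutually exclusive treatment-combination states.
COMBINATION_STATES: tuple[str, ...] = (
    "None", "GC", "HCQ", "IS", "HCQ+GC", "IS+GC", "IS+HCQ", "IS+HCQ+GC",
)


@dataclass(frozen=True)
class GCSubstance:
    """Prednisolone-equivalence entry for one oral glucocorticoid."""

    name: str
    factor: float  # mg prednisolone-equivalent per mg of substance
    ddd_mg: float  # WHO DDD, mg of substance per defined daily dose

    def __post_init__(self) -> None:
        if self.factor <= 0 or self.ddd_mg <= 0:
            raise ValueError(f"factor and ddd_mg must be > 0 for {self.name}")


@dataclass(frozen=True)
class EquivalenceTable:
    """ATC -> prednisolone-equivalence factors and DDD sizes.

    Defaults use the conventional anti-inflammatory potency ratios relative
    to prednisolone (factor 1.0) and WHO ATC/DDD index DDD values; both are
    fully configurable. One DDD of dispensed substance contributes
    ``ddd_mg * factor`` mg on the prednisolone scale.
    """

    substances: dict[str, GCSubstance] = field(default_factory=lambda: {
        "H02AB01": GCSubstance("betamethasone", 8.33, 1.5),
        "H02AB02": GCSubstance("dexamethasone", 6.67, 1.5),
        "H02AB04": GCSubstance("methylprednisolone", 1.25, 7.5),
        "H02AB06": GCSubstance("prednisolone", 1.0, 10.0),
        "H02AB07": GCSubstance("prednisone", 1.0, 10.0),
        "H02AB09": GCSubstance("hydrocortisone", 0.25, 30.0),
        "H02AB10": GCSubstance("cortisone", 0.2, 37.5),
    })

    def __post_init__(self) -> None:
        pred = self.substances.get("H02AB06")
        if pred is not None and pred.factor != 1.0:
            raise ValueError("prednisolone must map to factor 1.0")

    def mg_per_ddd(self, atc_code: str) -> float:
        """Prednisolone-equivalent mg contributed by one DDD of ``atc_code``."""
        try:
            sub = self.substances[atc_code]
        except KeyError:
            raise KeyError(
                f"ATC code {atc_code!r} missing from the GC equivalence table"
            ) from None
        return sub.ddd_mg * sub.factor


DEFAULT_EQUIVALENCE = EquivalenceTable()
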