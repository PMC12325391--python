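"""Compliance grading of national vs EU limit values, and risk screening.

The compliance grade of a sample is the ratio OCRI_Nat / OCRI_EU computed on
the six-metal subset (Cd, Cu, Hg, Ni, Pb, Zn), national limits against the
pH-banded EU limits.  Ratios below 0.80 mean the EU limits are the stricter
set; ratios above 1.30 mean the national transposition is stricter; the band
[0.80, 1.30] is a good balance (deviations of roughly 25-30% considered
acceptable).

Limit values themselves can additionally be screened against published median
soil screening values at three risk levels (negligible, intermediate/warning,
potentially unacceptable); limits above the intermediate level deserve
revision since harmful effects may occur before they are exceeded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .contamination_indices import OcriResult, assess_samples
from .limit_registry import LimitRegistry, Strategy
from .sample_model import METALS, SIX_METALS, Metal, SoilSample

EU_STRICTER_BELOW = 0.80
NATIONAL_STRICTER_ABOVE = 1.30


class ComplianceCategory(str, enum.Enum):
    eu_stricter = "eu_stricter"
    balanced = "balanced"
    national_stricter = "national_stricter"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ComplianceResult:
    """Per-sample national-vs-EU grade with per-metal detail ratios."""

    sample_id: str
    ratio: float
    category: ComplianceCategory
    per_metal_ratios: Mapping[Metal, float]


def categorize_ratio(ratio: float) -> ComplianceCategory:
    """Map a positive OCRI_Nat/OCRI_EU ratio to its compliance category.

    The boundaries 0.80 and 1.30 belong to the balanced band.
    """
    if ratio < EU_STRICTER_BELOW:
        return ComplianceCategory.eu_stricter
    if ratio > NATIONAL_STRICTER_ABOVE:
        return ComplianceCategory.national_stricter
    return ComplianceCategory.balanced


def compliance_grade(ocri_nat: OcriResult, ocri_eu: OcriResult) -> ComplianceResult:
    """Grade one sample from its paired national and EU overall indices.

    Both OCRIs must come from the same sample, computed on the six-metal
    subset.  Per-metal ratios use the capped single indices and are present
    only where both sides evaluated the metal.
    """
    if ocri_nat.sample_id != ocri_eu.sample_id:
        raise ValueError(
            f"mismatched samples: {ocri_nat.sample_id!r} vs {ocri_eu.sample_id!r}"
        )
    ratio = ocri_nat.ocri / ocri_eu.ocri
    per_metal = {}
    for m in METALS:
        nat, eu = ocri_nat.cris.get(m), ocri_eu.cris.get(m)
        if nat is not None and eu is not None:
            per_metal[m] = nat.cri / eu.cri
    return ComplianceResult(
        sample_id=ocri_nat.sample_id,
        ratio=ratio,
        category=categorize_ratio(ratio),
        per_metal_ratios=per_metal,
    )


def grade_samples(
    samples: Sequence[SoilSample], reg: LimitRegistry
) -> list[ComplianceResult]:
    """Grade each sample: national (strategy III) vs pH-banded EU (strategy II),
    six-metal subset on both sides."""
    nat = assess_samples(samples, Strategy.NATIONAL, reg, SIX_METALS)
    eu = assess_samples(samples, Strategy.EU_PH, reg, SIX_METALS)
    return [compliance_grade(n, e) for n, e in zip(nat, eu)]


def compliance_frame(results: Sequence[ComplianceResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict[str, object] = {
            "sample_id": r.sample_id,
            "ratio": r.ratio,
            "category": r.category.value,
        }
        for m in METALS:
            row[f"ratio_{m.value}"] = r.per_metal_ratios.get(m)
        rows.append(row)
    columns = ["sample_id", "ratio", "category"] + [
        f"ratio_{m.value}" for m in METALS
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Risk screening against published soil screening value medians


@dataclass(frozen=True)
class RiskBand:
    """Median soil screening values (mg kg^-1) at the three risk levels."""

    metal: Metal
    negligible_median: float
    intermediate_median: float
    unacceptable_median: float

    def __post_init__(self) -> None:
        if not (
            self.negligible_median
            < self.intermediate_median
            < self.unacceptable_median
        ):
            raise ValueError(
                f"{self.metal.value}: risk medians must increase strictly"
            )


#: Median screening values across European national systems (Carlon's review),
#: negligible / intermediate-warning / potentially unacceptable risk.
CARLON_RISK_BANDS: dict[Metal, RiskBand] = {
    m: RiskBand(m, *vals)
    for m, vals in {
        Metal.As: (29.0, 30.0, 50.0),
        Metal.Cd: (0.7, 3.0, 6.0),
        Metal.Cr: (115.0, 250.0, 275.0),
        Metal.Cu: (36.0, 110.0, 345.0),
        Metal.Hg: (0.3, 2.5, 10.0),
        Metal.Ni: (35.0, 140.0, 175.0),
        Metal.Pb: (83.0, 195.0, 450.0),
        Metal.Zn: (140.0, 500.0, 700.0),
    }.items()
}


class RiskLevel(str, enum.Enum):
    below_negligible = "below_negligible"
    negligible_to_intermediate = "negligible_to_intermediate"
    intermediate_to_unacceptable = "intermediate_to_unacceptable"
    above_unacceptable = "above_unacceptable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_lv_risk(
    metal: Metal, lv: float, bands: RiskBand | None = None
) -> RiskLevel:
    """Band a limit value against the risk-level medians for its metal.

    Intervals are lower-exclusive/upper-inclusive, so a limit exactly at the
    intermediate median still counts as negligible-to-intermediate.
    """
    if not lv > 0:
        raise ValueError(f"limit value must be positive, got {lv}")
    band = CARLON_RISK_BANDS[metal] if bands is None else bands
    if lv <= band.negligible_median:
        return RiskLevel.below_negligible
    if lv <= band.intermediate_median:
        return RiskLevel.negligible_to_intermediate
    if lv <= band.unacceptable_median:
        return RiskLevel.intermediate_to_unacceptable
    return RiskLevel.above_unacceptable


def screen_registry(
    reg: LimitRegistry, bands: Mapping[Metal, RiskBand] | None = None
) -> pd.DataFrame:
    """Band every limit value in a registry: one row per (set, metal)."""
    bands = CARLON_RISK_BANDS if bands is None else bands
    rows = []
    for s in reg.sets:
        for m in METALS:
            lv = s.limit(m)
            if lv is None:
                continue
            rows.append(
                {
                    "set_id": s.set_id,
                    "strategy": s.strategy.value,
                    "jurisdiction": s.jurisdiction,
                    "selector": s.selector.describe(),
                    "metal": m.value,
                    "limit_value": lv,
                    "risk_level": classify_lv_risk(m, lv, bands[m]).value,
                }
            )
    return pd.DataFrame(rows)
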