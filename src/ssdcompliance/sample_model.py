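"""Topsoil sample data model, CSV I/O, validation, and below-LOQ imputation.

A record represents one georeferenced composite topsoil sample with pH (in
water), particle-size fractions, and aqua-regia pseudototal concentrations of
eight heavy metals in mg kg^-1 dry matter.  Concentrations below the limit of
quantification (LOQ) are censored and substituted by half the LOQ, the
convention used throughout large-scale European topsoil surveys.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TEXTURE_SUM_TOL = 1.0  # percentage points around 100 for clay+silt+sand


class Metal(str, enum.Enum):
    """The eight metals regulated (or proposed) for sludge-amended soils.

    Ordering is fixed and used to break ties deterministically.
    """

    As = "As"
    Cd = "Cd"
    Cr = "Cr"
    Cu = "Cu"
    Hg = "Hg"
    Ni = "Ni"
    Pb = "Pb"
    Zn = "Zn"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


METALS: tuple[Metal, ...] = tuple(Metal)

#: Metals with fixed EU limit values under the pH-independent strategies.
EIGHT_METALS: tuple[Metal, ...] = METALS

#: Subset used by the pH-dependent EU strategy and the compliance grade
#: (As and Cr have no pH-banded EU limits).
SIX_METALS: tuple[Metal, ...] = (
    Metal.Cd,
    Metal.Cu,
    Metal.Hg,
    Metal.Ni,
    Metal.Pb,
    Metal.Zn,
)

#: ICP-OES limits of quantification, mg kg^-1 dry matter.
DEFAULT_LOQ: dict[Metal, float] = {
    Metal.As: 2.84,
    Metal.Cd: 0.07,
    Metal.Cr: 0.32,
    Metal.Cu: 0.26,
    Metal.Hg: 0.054,
    Metal.Ni: 0.27,
    Metal.Pb: 1.16,
    Metal.Zn: 2.12,
}

LAND_COVERS = ("cropland", "grassland", "other")
AGRICULTURAL_LAND_COVERS = ("cropland", "grassland")

CSV_COLUMNS = (
    "sample_id",
    "country",
    "nuts2",
    "region_code",
    "land_cover",
    "ph_h2o",
    "clay_pct",
    "silt_pct",
    "sand_pct",
) + tuple(m.value for m in METALS)


class SchemaError(ValueError):
    """The input table is missing a mandatory column."""


class ValidationError(ValueError):
    """A row violates a field-level invariant."""


def validate_loq(loq: Mapping[Metal, float]) -> dict[Metal, float]:
    """Check an LOQ table: all eight metals present, all values positive."""
    missing = [m.value for m in METALS if m not in loq]
    if missing:
        raise ValidationError(f"LOQ table missing metals: {missing}")
    bad = {m.value: v for m, v in loq.items() if not v > 0}
    if bad:
        raise ValidationError(f"LOQ values must be positive: {bad}")
    return {m: float(loq[m]) for m in METALS}


@dataclass(frozen=True)
class MetalMeasurement:
    """One pseudototal concentration, possibly censored below the LOQ.

    ``effective_value`` is the concentration used by all downstream indices:
    the raw value when quantified, half the LOQ when censored, absent when the
    metal was not determined.
    """

    metal: Metal
    raw_value: float | None = None
    censored: bool = False
    effective_value: float | None = None

    def __post_init__(self) -> None:
        if self.raw_value is not None and self.raw_value < 0:
            raise ValidationError(
                f"{self.metal.value}: negative concentration {self.raw_value}"
            )

    @property
    def present(self) -> bool:
        return self.effective_value is not None


def impute_below_loq(
    m: MetalMeasurement, loq: Mapping[Metal, float] | None = None
) -> MetalMeasurement:
    """Substitute half the LOQ for a censored measurement.

    Uncensored measurements get their raw value as effective value; absent
    measurements stay absent.  Idempotent.
    """
    loq = DEFAULT_LOQ if loq is None else loq
    if m.censored:
        return replace(m, effective_value=loq[m.metal] / 2.0)
    if m.raw_value is not None:
        return replace(m, effective_value=m.raw_value)
    return replace(m, effective_value=None)


@dataclass(frozen=True)
class SoilSample:
    """One topsoil record: location codes, soil criteria, and measurements."""

    sample_id: str
    country: str
    nuts2: str | None = None
    region_code: str | None = None
    land_cover: str = "other"
    ph_h2o: float | None = None
    clay_pct: float | None = None
    silt_pct: float | None = None
    sand_pct: float | None = None
    measurements: Mapping[Metal, MetalMeasurement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.land_cover not in LAND_COVERS:
            raise ValidationError(
                f"{self.sample_id}: unknown land_cover {self.land_cover!r}"
            )
        if self.ph_h2o is not None and not (0.0 < self.ph_h2o < 14.0):
            raise ValidationError(
                f"{self.sample_id}: pH {self.ph_h2o} outside (0, 14)"
            )
        fracs = (self.clay_pct, self.silt_pct, self.sand_pct)
        for name, v in zip(("clay_pct", "silt_pct", "sand_pct"), fracs):
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValidationError(f"{self.sample_id}: {name}={v} outside [0, 100]")
        if all(v is not None for v in fracs):
            total = sum(fracs)  # type: ignore[arg-type]
            if abs(total - 100.0) > TEXTURE_SUM_TOL:
                raise ValidationError(
                    f"{self.sample_id}: texture fractions sum to {total:.2f}, "
                    f"not 100 +/- {TEXTURE_SUM_TOL}"
                )

    @property
    def has_texture(self) -> bool:
        return all(
            v is not None for v in (self.clay_pct, self.silt_pct, self.sand_pct)
        )

    def measurement(self, metal: Metal) -> MetalMeasurement | None:
        m = self.measurements.get(metal)
        if m is not None and m.present:
            return m
        return None


def _parse_float(cell: object, what: str, sample_id: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"{sample_id}: non-numeric {what} {text!r}") from None


def _parse_measurement(
    cell: object, metal: Metal, loq: Mapping[Metal, float], sample_id: str
) -> MetalMeasurement:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return MetalMeasurement(metal)
    text = str(cell).strip()
    if text == "":
        return MetalMeasurement(metal)
    if text.startswith("<"):
        # Censored cell.  The numeric tail is ignored: one fixed LOQ per
        # metal governs the substitution.
        return impute_below_loq(MetalMeasurement(metal, censored=True), loq)
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(
            f"{sample_id}: non-numeric {metal.value} concentration {text!r}"
        ) from None
    return impute_below_loq(MetalMeasurement(metal, raw_value=value), loq)


def _row_to_sample(
    row: Mapping[str, object], loq: Mapping[Metal, float]
) -> SoilSample:
    sample_id = str(row["sample_id"]).strip()

    def opt_str(key: str) -> str | None:
        v = row.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        text = str(v).strip()
        return text or None

    measurements = {
        m: _parse_measurement(row.get(m.value), m, loq, sample_id) for m in METALS
    }
    return SoilSample(
        sample_id=sample_id,
        country=(opt_str("country") or ""),
        nuts2=opt_str("nuts2"),
        region_code=opt_str("region_code"),
        land_cover=(opt_str("land_cover") or "other"),
        ph_h2o=_parse_float(row.get("ph_h2o"), "ph_h2o", sample_id),
        clay_pct=_parse_float(row.get("clay_pct"), "clay_pct", sample_id),
        silt_pct=_parse_float(row.get("silt_pct"), "silt_pct", sample_id),
        sand_pct=_parse_float(row.get("sand_pct"), "sand_pct", sample_id),
        measurements=measurements,
    )


def read_samples(
    path: str | Path,
    loq: Mapping[Metal, float] | None = None,
    errors: list[tuple[int, str]] | None = None,
) -> list[SoilSample]:
    """Read topsoil records from CSV.

    Concentration cells may be numeric, empty (metal not determined), or
    ``"<x"`` strings (censored below the LOQ).  Row order is preserved.
    Rows violating field invariants are rejected and logged; pass a list as
    ``errors`` to collect ``(row_number, message)`` pairs.

    Raises
    ------
    SchemaError
        If a mandatory column is missing from the header.
    """
    loq = validate_loq(DEFAULT_LOQ if loq is None else loq)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    samples: list[SoilSample] = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        try:
            samples.append(_row_to_sample(row, loq))
        except ValidationError as exc:
            logger.warning("row %d rejected: %s", i + 2, exc)
            if errors is not None:
                errors.append((i + 2, str(exc)))
    return samples


def _format_cell(m: MetalMeasurement, loq: Mapping[Metal, float]) -> str:
    if m.censored:
        return f"<{loq[m.metal]:g}"
    if m.raw_value is None:
        return ""
    return repr(m.raw_value)


def write_samples(
    samples: Iterable[SoilSample],
    path: str | Path,
    loq: Mapping[Metal, float] | None = None,
) -> None:
    """Write records to CSV in the canonical column schema.

    Round-trips with :func:`read_samples`: all field values of valid rows are
    reproduced exactly (floats are written with full precision).
    """
    loq = validate_loq(DEFAULT_LOQ if loq is None else loq)
    rows = []
    for s in samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "country": s.country,
            "nuts2": s.nuts2 or "",
            "region_code": s.region_code or "",
            "land_cover": s.land_cover,
            "ph_h2o": "" if s.ph_h2o is None else repr(s.ph_h2o),
            "clay_pct": "" if s.clay_pct is None else repr(s.clay_pct),
            "silt_pct": "" if s.silt_pct is None else repr(s.silt_pct),
            "sand_pct": "" if s.sand_pct is None else repr(s.sand_pct),
        }
        for m in METALS:
            meas = s.measurements.get(m, MetalMeasurement(m))
            row[m.value] = _format_cell(meas, loq)
        rows.append(row)
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def filter_agricultural(
    samples: Sequence[SoilSample],
) -> list[SoilSample]:
    """Keep cropland and grassland records, the survey's agricultural points."""
    kept = [s for s in samples if s.land_cover in AGRICULTURAL_LAND_COVERS]
    removed = len(samples) - len(kept)
    if removed:
        logger.info("filter_agricultural: removed %d non-agricultural rows", removed)
    return kept
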