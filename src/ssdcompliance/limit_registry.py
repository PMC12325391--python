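"""Limit-value regimes for heavy metals in sludge-amended agricultural soil.

Three resolution strategies are supported:

* ``EU_LL`` / ``EU_UL`` -- the Directive's fixed lower/upper limit values
  (with cross-national average substitutes for As and Cr, which the Directive
  does not set);
* ``EU_PH`` -- the Directive's pH-banded limits (acid / neutral / alkaline
  soils; no As or Cr limits exist in this regime);
* ``NATIONAL`` -- the 48 national and regional transpositions, some of which
  band their limits by soil pH or by national texture category.

The registry ships as a reviewable plain-text transcription
(``data/limit_values.csv``); :func:`build_registry` validates its structural
invariants (pH bands partition the pH axis, texture selectors cover their
scheme, no duplicate selectors).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .sample_model import METALS, Metal, SoilSample
from .texture_classifier import (
    SCHEME_CATEGORIES,
    TextureScheme,
    classify_usda,
    map_national,
)

PH_DOMAIN = (0.0, 14.0)

#: ISO alpha-2 spellings accepted for jurisdictions keyed by NUTS0 code.
COUNTRY_ALIASES = {"GR": "EL", "GB": "UK"}


class RegistryError(ValueError):
    """The registry source violates a structural invariant."""


class ResolutionError(LookupError):
    """No applicable limit-value set could be determined for a sample."""


class Strategy(str, enum.Enum):
    EU_LL = "EU_LL"
    EU_UL = "EU_UL"
    EU_PH = "EU_PH"
    NATIONAL = "NATIONAL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SelectorKind(str, enum.Enum):
    none = "none"
    ph_band = "ph_band"
    texture_category = "texture_category"


@dataclass(frozen=True)
class Selector:
    """Condition under which one limit-value set applies within a regime."""

    kind: SelectorKind = SelectorKind.none
    ph_low: float | None = None
    ph_low_closed: bool = False
    ph_high: float | None = None
    ph_high_closed: bool = False
    texture_scheme: TextureScheme | None = None
    texture_category: str | None = None

    def matches_ph(self, ph: float) -> bool:
        assert self.kind is SelectorKind.ph_band
        lo_ok = ph > self.ph_low or (self.ph_low_closed and ph == self.ph_low)
        hi_ok = ph < self.ph_high or (self.ph_high_closed and ph == self.ph_high)
        return lo_ok and hi_ok

    def describe(self) -> str:
        if self.kind is SelectorKind.ph_band:
            lo = "[" if self.ph_low_closed else "("
            hi = "]" if self.ph_high_closed else ")"
            return f"pH {lo}{self.ph_low:g}, {self.ph_high:g}{hi}"
        if self.kind is SelectorKind.texture_category:
            return f"{self.texture_scheme.value}:{self.texture_category}"
        return "unconditional"


@dataclass(frozen=True)
class LimitValueSet:
    """One jurisdiction-specific set of per-metal limit values (mg kg^-1)."""

    set_id: str
    strategy: Strategy
    jurisdiction: str
    selector: Selector = field(default_factory=Selector)
    limits: Mapping[Metal, float] = field(default_factory=dict)
    substituted: frozenset[Metal] = frozenset()

    def __post_init__(self) -> None:
        bad = {m.value: v for m, v in self.limits.items() if not v > 0}
        if bad:
            raise RegistryError(f"{self.set_id}: non-positive limits {bad}")

    def limit(self, metal: Metal) -> float | None:
        return self.limits.get(metal)


class LimitRegistry:
    """Indexed collection of limit-value sets with per-sample resolution."""

    def __init__(self, sets: Iterable[LimitValueSet]):
        self.sets: list[LimitValueSet] = list(sets)
        self._index: dict[tuple[Strategy, str], list[LimitValueSet]] = {}
        for s in self.sets:
            self._index.setdefault((s.strategy, s.jurisdiction), []).append(s)
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        for (strategy, jurisdiction), sets in self._index.items():
            kinds = {s.selector.kind for s in sets}
            if len(kinds) > 1:
                raise RegistryError(
                    f"{strategy}/{jurisdiction}: mixed selector kinds {kinds}"
                )
            kind = next(iter(kinds))
            if kind is SelectorKind.none:
                if len(sets) > 1:
                    raise RegistryError(
                        f"{strategy}/{jurisdiction}: duplicate unconditional sets"
                    )
            elif kind is SelectorKind.ph_band:
                self._check_ph_partition(strategy, jurisdiction, sets)
            else:
                self._check_texture_cover(strategy, jurisdiction, sets)

    @staticmethod
    def _check_ph_partition(
        strategy: Strategy, jurisdiction: str, sets: list[LimitValueSet]
    ) -> None:
        bands = sorted(sets, key=lambda s: s.selector.ph_low)
        lo, hi = PH_DOMAIN
        if bands[0].selector.ph_low != lo or bands[-1].selector.ph_high != hi:
            raise RegistryError(
                f"{strategy}/{jurisdiction}: pH bands do not span ({lo}, {hi})"
            )
        for a, b in zip(bands, bands[1:]):
            if a.selector.ph_high != b.selector.ph_low:
                raise RegistryError(
                    f"{strategy}/{jurisdiction}: pH bands gap/overlap at "
                    f"{a.selector.ph_high} vs {b.selector.ph_low}"
                )
            if a.selector.ph_high_closed == b.selector.ph_low_closed:
                raise RegistryError(
                    f"{strategy}/{jurisdiction}: pH cut point "
                    f"{a.selector.ph_high} claimed by both or neither band"
                )

    @staticmethod
    def _check_texture_cover(
        strategy: Strategy, jurisdiction: str, sets: list[LimitValueSet]
    ) -> None:
        schemes = {s.selector.texture_scheme for s in sets}
        if len(schemes) != 1:
            raise RegistryError(
                f"{strategy}/{jurisdiction}: mixed texture schemes {schemes}"
            )
        scheme = next(iter(schemes))
        cats = [s.selector.texture_category for s in sets]
        if sorted(cats) != sorted(SCHEME_CATEGORIES[scheme]):
            raise RegistryError(
                f"{strategy}/{jurisdiction}: texture categories {cats} do not "
                f"cover scheme {scheme.value}"
            )

    # -- access ------------------------------------------------------------

    def sets_for(self, strategy: Strategy, jurisdiction: str) -> list[LimitValueSet]:
        return self._index.get((Strategy(strategy), jurisdiction), [])

    def jurisdictions(self, strategy: Strategy) -> list[str]:
        strategy = Strategy(strategy)
        return sorted(
            {j for (s, j) in self._index if s is strategy}
        )

    def national_set_count(self) -> int:
        return sum(1 for s in self.sets if s.strategy is Strategy.NATIONAL)


def _flag_set(text: str) -> frozenset[Metal]:
    if not text:
        return frozenset()
    return frozenset(Metal(tok) for tok in text.split(";") if tok)


def build_registry(source: str | Path | None = None) -> LimitRegistry:
    """Build a registry from a delimited transcription file.

    With ``source=None`` the packaged transcription of the national, regional,
    and EU limit-value sets is used.
    """
    if source is None:
        source = resources.files("ssdcompliance.data") / "limit_values.csv"
        with resources.as_file(source) as path:
            frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)

    sets = []
    seen: set[str] = set()
    for row in frame.to_dict(orient="records"):
        set_id = row["set_id"]
        if set_id in seen:
            raise RegistryError(f"duplicate set_id {set_id}")
        seen.add(set_id)
        kind = SelectorKind(row["selector_kind"])
        selector = Selector(
            kind=kind,
            ph_low=float(row["ph_low"]) if row["ph_low"] else None,
            ph_low_closed=row["ph_low_closed"] == "1",
            ph_high=float(row["ph_high"]) if row["ph_high"] else None,
            ph_high_closed=row["ph_high_closed"] == "1",
            texture_scheme=(
                TextureScheme(row["texture_scheme"]) if row["texture_scheme"] else None
            ),
            texture_category=row["texture_category"] or None,
        )
        limits = {
            m: float(row[m.value]) for m in METALS if row[m.value].strip() != ""
        }
        sets.append(
            LimitValueSet(
                set_id=set_id,
                strategy=Strategy(row["strategy"]),
                jurisdiction=row["jurisdiction"],
                selector=selector,
                limits=limits,
                substituted=_flag_set(row["substituted_flags"]),
            )
        )
    registry = LimitRegistry(sets)
    _check_eu_sets(registry)
    return registry


def _check_eu_sets(reg: LimitRegistry) -> None:
    for strategy in (Strategy.EU_LL, Strategy.EU_UL):
        for s in reg.sets_for(strategy, "EU"):
            missing = [m.value for m in METALS if m not in s.limits]
            if missing:
                raise RegistryError(f"{s.set_id}: missing metals {missing}")
            if not {Metal.As, Metal.Cr} <= s.substituted:
                raise RegistryError(f"{s.set_id}: As/Cr must be flagged substituted")
    for s in reg.sets_for(Strategy.EU_PH, "EU"):
        present = {Metal.As, Metal.Cr} & set(s.limits)
        if present:
            raise RegistryError(
                f"{s.set_id}: pH-banded EU regime must omit As/Cr, has {present}"
            )


_DEFAULT_REGISTRY: LimitRegistry | None = None


def default_registry() -> LimitRegistry:
    """The packaged registry, built once and cached."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = build_registry(None)
    return _DEFAULT_REGISTRY


def jurisdiction_for(reg: LimitRegistry, sample: SoilSample) -> str:
    """Jurisdiction key governing a sample under the national strategy.

    A sub-national ``region_code`` naming a regional regime (Austrian Laender,
    Belgian regions) wins over the country code; Austria without a matching
    region falls back to the rest-of-the-regions set.
    """
    if sample.region_code and reg.sets_for(Strategy.NATIONAL, sample.region_code):
        return sample.region_code
    country = COUNTRY_ALIASES.get(sample.country, sample.country)
    if reg.sets_for(Strategy.NATIONAL, country):
        return country
    raise ResolutionError(
        f"{sample.sample_id}: no national limit-value regime for country "
        f"code {sample.country!r} (region_code={sample.region_code!r})"
    )


def _select_set(
    reg: LimitRegistry, strategy: Strategy, jurisdiction: str, sample: SoilSample
) -> LimitValueSet:
    sets = reg.sets_for(strategy, jurisdiction)
    if not sets:
        raise ResolutionError(
            f"{sample.sample_id}: unknown jurisdiction {jurisdiction!r} "
            f"under strategy {strategy}"
        )
    kind = sets[0].selector.kind
    if kind is SelectorKind.none:
        return sets[0]
    if kind is SelectorKind.ph_band:
        if sample.ph_h2o is None:
            raise ResolutionError(
                f"{sample.sample_id}: regime {strategy}/{jurisdiction} is "
                "pH-banded but the sample has no pH"
            )
        for s in sets:
            if s.selector.matches_ph(sample.ph_h2o):
                return s
        raise ResolutionError(  # pragma: no cover - partition guarantees a match
            f"{sample.sample_id}: no pH band matches {sample.ph_h2o}"
        )
    # texture-banded
    if not sample.has_texture:
        raise ResolutionError(
            f"{sample.sample_id}: regime {strategy}/{jurisdiction} is "
            "texture-banded but the sample has no texture fractions"
        )
    scheme = sets[0].selector.texture_scheme
    usda = classify_usda(sample.sand_pct, sample.silt_pct, sample.clay_pct)
    category = map_national(usda, scheme)
    for s in sets:
        if s.selector.texture_category == category:
            return s
    raise ResolutionError(  # pragma: no cover - coverage check guarantees a match
        f"{sample.sample_id}: no texture category set for {category}"
    )


def resolve_set(
    reg: LimitRegistry, strategy: Strategy | str, sample: SoilSample
) -> LimitValueSet:
    """The unique limit-value set applicable to a sample under a strategy."""
    strategy = Strategy(strategy)
    if strategy is Strategy.NATIONAL:
        jurisdiction = jurisdiction_for(reg, sample)
    else:
        jurisdiction = "EU"
    return _select_set(reg, strategy, jurisdiction, sample)


def resolve_limit(
    reg: LimitRegistry,
    strategy: Strategy | str,
    sample: SoilSample,
    metal: Metal,
) -> float | None:
    """The applicable limit value in mg kg^-1, or None where the regime
    defines no limit for that metal (e.g. As/Cr under the pH-banded EU
    regime)."""
    return resolve_set(reg, strategy, sample).limit(metal)
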