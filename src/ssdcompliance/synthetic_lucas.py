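"""Synthetic survey-like topsoil datasets with controlled statistical structure.

The generator emulates the *shape* of a harmonised European topsoil survey —
per-country lognormal metal concentrations, truncated-normal pH spanning the
acid/neutral/alkaline bands, Dirichlet texture fractions summing to 100,
below-LOQ censoring at the instrument's quantification limits, and optional
*planted* exceedances whose status is known by construction — so that every
pipeline stage is testable without the registration-gated real survey.

Default parameter magnitudes are test scaffolding chosen to span both sides
of the fixed EU lower limits; they are not estimates of real European soil
distributions.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .limit_registry import (
    LimitRegistry,
    ResolutionError,
    Strategy,
    default_registry,
    resolve_limit,
)
from .sample_model import (
    DEFAULT_LOQ,
    METALS,
    Metal,
    MetalMeasurement,
    SoilSample,
    impute_below_loq,
    read_samples,
    validate_loq,
)


class ConfigError(ValueError):
    """The generator configuration is inconsistent or unresolvable."""


@dataclass(frozen=True)
class PlantedExceedance:
    """Plant a known fraction of exceedances for one metal.

    Selected samples draw their concentration uniformly in
    ``(1, 2] * limit``, where the limit is resolved under ``strategy`` for
    the sample itself, so the exceedance status is true by construction.
    """

    metal: Metal
    fraction: float
    strategy: Strategy = Strategy.EU_LL

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError(f"planted fraction {self.fraction} outside [0, 1]")


@dataclass(frozen=True)
class CountryConfig:
    """Generating distributions for one country block."""

    country: str
    n: int
    nuts2_weights: Mapping[str, float]
    #: Metal -> (mean, sd) of log concentration (natural log, mg kg^-1).
    metal_lognorm: Mapping[Metal, tuple[float, float]]
    #: (mean, sd, low, high) of a truncated normal pH distribution.
    ph: tuple[float, float, float, float] = (6.5, 1.0, 3.5, 9.5)
    #: Dirichlet concentrations for (sand, silt, clay).
    texture_alpha: tuple[float, float, float] = (4.0, 4.0, 2.0)
    land_cover_probs: Mapping[str, float] = field(
        default_factory=lambda: {"cropland": 0.6, "grassland": 0.4}
    )
    region_code: str | None = None
    planted: PlantedExceedance | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"{self.country}: n must be >= 1")
        for m, (mu, sd) in self.metal_lognorm.items():
            if sd <= 0:
                raise ConfigError(f"{self.country}/{m.value}: log-sd must be > 0")
        for probs, what in (
            (self.nuts2_weights, "nuts2_weights"),
            (self.land_cover_probs, "land_cover_probs"),
        ):
            total = sum(probs.values())
            if not probs or abs(total - 1.0) > 1e-6:
                raise ConfigError(
                    f"{self.country}: {what} must be non-empty and sum to 1, "
                    f"got {total}"
                )


@dataclass(frozen=True)
class GeneratorConfig:
    countries: tuple[CountryConfig, ...]
    seed: int = 0
    loq: Mapping[Metal, float] = field(default_factory=lambda: dict(DEFAULT_LOQ))


@dataclass(frozen=True)
class GenerationResult:
    """Samples plus the generation log of true planted-exceedance labels."""

    samples: list[SoilSample]
    truth: pd.DataFrame


def _country_rng(seed: int, country: str) -> np.random.Generator:
    """Per-country substream: adding a country never perturbs the others."""
    return np.random.default_rng(
        np.random.SeedSequence((seed, zlib.crc32(country.encode())))
    )


def _draw_texture(rng: np.random.Generator, alpha) -> tuple[float, float, float]:
    sand, silt, clay = (float(x) for x in 100.0 * rng.dirichlet(alpha))
    # Round-and-repair: round two fractions, assign the remainder to the
    # third so the triple sums to exactly 100.
    sand, silt = round(sand, 2), round(silt, 2)
    clay = round(100.0 - sand - silt, 2)
    if clay < 0.0:  # rounding pushed the pair above 100
        sand = round(sand + clay, 2)
        clay = 0.0
    return sand, silt, clay


def _measurement(
    metal: Metal, value: float, loq: Mapping[Metal, float]
) -> MetalMeasurement:
    # Censoring mimics the instrument: draw, then compare to the LOQ.
    if value < loq[metal]:
        return impute_below_loq(MetalMeasurement(metal, censored=True), loq)
    return impute_below_loq(MetalMeasurement(metal, raw_value=value), loq)


def generate(
    config: GeneratorConfig, registry: LimitRegistry | None = None
) -> GenerationResult:
    """Generate a synthetic dataset; reproducible for a fixed seed.

    The returned truth table records, per sample, whether an exceedance was
    planted and for which metal/strategy/limit, so pipeline flags can be
    checked against construction.
    """
    reg = default_registry() if registry is None else registry
    loq = validate_loq(config.loq)
    samples: list[SoilSample] = []
    truth_rows: list[dict[str, object]] = []
    for cc in config.countries:
        rng = _country_rng(config.seed, cc.country)
        nuts2_codes = list(cc.nuts2_weights)
        nuts2_p = np.array([cc.nuts2_weights[c] for c in nuts2_codes], dtype=float)
        nuts2_p /= nuts2_p.sum()
        covers = list(cc.land_cover_probs)
        cover_p = np.array([cc.land_cover_probs[c] for c in covers], dtype=float)
        cover_p /= cover_p.sum()
        mean, sd, low, high = cc.ph
        ph_values = stats.truncnorm.rvs(
            (low - mean) / sd, (high - mean) / sd, loc=mean, scale=sd,
            size=cc.n, random_state=rng,
        )
        for i in range(cc.n):
            sample_id = f"{cc.country}{i:05d}"
            sand, silt, clay = _draw_texture(rng, cc.texture_alpha)
            concentrations = {
                m: float(rng.lognormal(mu, s))
                for m, (mu, s) in cc.metal_lognorm.items()
            }
            planted = (
                cc.planted is not None and rng.random() < cc.planted.fraction
            )
            sample = SoilSample(
                sample_id=sample_id,
                country=cc.country,
                nuts2=str(rng.choice(nuts2_codes, p=nuts2_p)),
                region_code=cc.region_code,
                land_cover=str(rng.choice(covers, p=cover_p)),
                ph_h2o=float(ph_values[i]),
                clay_pct=clay,
                silt_pct=silt,
                sand_pct=sand,
                measurements={},
            )
            planted_limit = None
            if planted:
                try:
                    planted_limit = resolve_limit(
                        reg, cc.planted.strategy, sample, cc.planted.metal
                    )
                except ResolutionError as exc:
                    raise ConfigError(
                        f"{cc.country}: planted exceedance unresolvable: {exc}"
                    ) from exc
                if planted_limit is None:
                    raise ConfigError(
                        f"{cc.country}: no {cc.planted.metal.value} limit under "
                        f"{cc.planted.strategy} to plant against"
                    )
                # u in (1, 2]: strictly above the limit.
                concentrations[cc.planted.metal] = float(
                    planted_limit * (2.0 - rng.random())
                )
            measurements = {
                m: _measurement(m, v, loq) for m, v in concentrations.items()
            }
            sample = SoilSample(
                sample_id=sample.sample_id,
                country=sample.country,
                nuts2=sample.nuts2,
                region_code=sample.region_code,
                land_cover=sample.land_cover,
                ph_h2o=sample.ph_h2o,
                clay_pct=sample.clay_pct,
                silt_pct=sample.silt_pct,
                sand_pct=sample.sand_pct,
                measurements=measurements,
            )
            samples.append(sample)
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "country": cc.country,
                    "planted": planted,
                    "planted_metal": (
                        cc.planted.metal.value if planted else None
                    ),
                    "planted_strategy": (
                        cc.planted.strategy.value if planted else None
                    ),
                    "planted_limit": planted_limit,
                    "planted_concentration": (
                        concentrations[cc.planted.metal] if planted else None
                    ),
                }
            )
    return GenerationResult(samples=samples, truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Config serialisation (YAML/JSON-compatible plain dicts)


def config_from_dict(data: Mapping) -> GeneratorConfig:
    countries = []
    for block in data["countries"]:
        planted = None
        if block.get("planted"):
            p = block["planted"]
            planted = PlantedExceedance(
                metal=Metal(p["metal"]),
                fraction=float(p["fraction"]),
                strategy=Strategy(p.get("strategy", "EU_LL")),
            )
        countries.append(
            CountryConfig(
                country=block["country"],
                n=int(block["n"]),
                nuts2_weights={
                    str(k): float(v) for k, v in block["nuts2_weights"].items()
                },
                metal_lognorm={
                    Metal(k): (float(v[0]), float(v[1]))
                    for k, v in block["metal_lognorm"].items()
                },
                ph=tuple(float(x) for x in block.get("ph", (6.5, 1.0, 3.5, 9.5))),
                texture_alpha=tuple(
                    float(x) for x in block.get("texture_alpha", (4.0, 4.0, 2.0))
                ),
                land_cover_probs={
                    str(k): float(v)
                    for k, v in block.get(
                        "land_cover_probs", {"cropland": 0.6, "grassland": 0.4}
                    ).items()
                },
                region_code=block.get("region_code"),
                planted=planted,
            )
        )
    loq = {
        Metal(k): float(v) for k, v in data.get("loq", {}).items()
    } or dict(DEFAULT_LOQ)
    return GeneratorConfig(
        countries=tuple(countries), seed=int(data.get("seed", 0)), loq=loq
    )


def load_config(path: str | Path) -> GeneratorConfig:
    """Load a generator configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


# Log-space parameters giving geometric means on realistic orders of
# magnitude, spanning both sides of the fixed EU lower limits (Ni and Cd sit
# close enough to produce exceedances; Hg straddles its LOQ so censoring is
# exercised).
_BASE_LOGNORM: dict[Metal, tuple[float, float]] = {
    Metal.As: (math.log(7.0), 0.7),
    Metal.Cd: (math.log(0.25), 0.8),
    Metal.Cr: (math.log(40.0), 0.6),
    Metal.Cu: (math.log(16.0), 0.7),
    Metal.Hg: (math.log(0.05), 0.8),
    Metal.Ni: (math.log(18.0), 0.7),
    Metal.Pb: (math.log(22.0), 0.6),
    Metal.Zn: (math.log(55.0), 0.6),
}


def default_config(seed: int = 0, n_per_country: int = 150) -> GeneratorConfig:
    """A moderate multi-country configuration exercising every regime kind:
    unconditional national sets (IE, FR, DK), pH-banded sets (ES), all three
    texture-banded schemes (DE, PL, CZ), and the Austrian regional fallback."""

    def block(country: str, nuts2: dict[str, float], **kw) -> CountryConfig:
        return CountryConfig(
            country=country,
            n=n_per_country,
            nuts2_weights=nuts2,
            metal_lognorm=dict(_BASE_LOGNORM),
            **kw,
        )

    countries = (
        block("IE", {"IE01": 0.4, "IE02": 0.6}, ph=(6.0, 0.8, 3.5, 8.5)),
        block("DE", {"DE11": 0.5, "DE21": 0.5}, ph=(6.3, 0.9, 3.5, 9.0)),
        block("PL", {"PL11": 0.5, "PL21": 0.5}, ph=(5.6, 0.8, 3.5, 8.5),
              texture_alpha=(6.0, 3.0, 1.5)),
        block("CZ", {"CZ01": 1.0}, ph=(6.4, 0.8, 3.5, 9.0)),
        block("FR", {"FR10": 0.5, "FR20": 0.5}, ph=(6.6, 1.0, 3.5, 9.5)),
        block("ES", {"ES30": 0.5, "ES61": 0.5}, ph=(7.2, 1.0, 3.5, 9.5)),
        block("DK", {"DK01": 1.0}, ph=(6.3, 0.7, 3.5, 8.5)),
        block("AT", {"AT22": 0.5, "AT34": 0.5}, ph=(6.2, 0.9, 3.5, 9.0)),
    )
    return GeneratorConfig(countries=countries, seed=seed)


def fixture_small() -> list[SoilSample]:
    """The packaged deterministic fixture: 18 samples covering each pH band,
    every national texture category, a missing-Hg record, a censored cell, an
    at-limit equality case, and one sample per compliance category."""
    from importlib import resources

    source = resources.files("ssdcompliance.data") / "fixture_small.csv"
    with resources.as_file(source) as path:
        return read_samples(path)
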