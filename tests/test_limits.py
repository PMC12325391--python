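"""Limit-value registry fidelity and per-sample resolution."""

import numpy as np
import pytest

from ssdcompliance import (
    Metal,
    SoilSample,
    Strategy,
    build_registry,
    jurisdiction_for,
    resolve_limit,
    resolve_set,
)
from ssdcompliance.limit_registry import (
    RegistryError,
    ResolutionError,
    SelectorKind,
)

REGISTRY_HEADER = (
    "set_id,strategy,jurisdiction,selector_kind,ph_low,ph_low_closed,"
    "ph_high,ph_high_closed,texture_scheme,texture_category,"
    "As,Cd,Cr,Cu,Hg,Ni,Pb,Zn,substituted_flags"
)


def make_sample(**kw):
    defaults = dict(
        sample_id="S", country="FR", land_cover="cropland", ph_h2o=6.5,
        clay_pct=20.0, silt_pct=40.0, sand_pct=40.0,
    )
    defaults.update(kw)
    return SoilSample(**defaults)


class TestRegistryStructure:
    def test_national_set_count(self, registry):
        assert registry.national_set_count() == 48

    def test_eu_lower_limits_exact(self, registry):
        (s,) = registry.sets_for(Strategy.EU_LL, "EU")
        assert s.limits == {
            Metal.As: 25.5, Metal.Cd: 1.0, Metal.Cr: 100.0, Metal.Cu: 50.0,
            Metal.Hg: 1.0, Metal.Ni: 30.0, Metal.Pb: 50.0, Metal.Zn: 150.0,
        }
        assert s.substituted == frozenset({Metal.As, Metal.Cr})

    def test_eu_upper_limits_exact(self, registry):
        (s,) = registry.sets_for(Strategy.EU_UL, "EU")
        assert s.limits == {
            Metal.As: 25.5, Metal.Cd: 3.0, Metal.Cr: 100.0, Metal.Cu: 140.0,
            Metal.Hg: 1.5, Metal.Ni: 75.0, Metal.Pb: 300.0, Metal.Zn: 300.0,
        }

    def test_ph_banded_eu_omits_as_cr(self, registry):
        for s in registry.sets_for(Strategy.EU_PH, "EU"):
            assert Metal.As not in s.limits and Metal.Cr not in s.limits

    def test_carinthia_bands(self, registry):
        sets = registry.sets_for(Strategy.NATIONAL, "AT-carinthia")
        assert len(sets) == 3
        cuts = sorted(s.selector.ph_high for s in sets)
        assert cuts == [5.5, 6.5, 14.0]

    def test_every_country_represented(self, registry):
        countries = {
            "AT", "BG", "CY", "CZ", "DK", "FI", "FR", "DE", "EL", "IE", "IT",
            "LU", "EE", "HU", "LV", "LT", "MT", "NL", "PT", "PL", "RO", "SK",
            "SI", "ES", "SE", "UK",
        }
        assert countries <= set(registry.jurisdictions(Strategy.NATIONAL))

    def test_substituted_flags(self, registry):
        # The rest-of-regions Austrian set is flagged substituted throughout.
        (at,) = registry.sets_for(Strategy.NATIONAL, "AT")
        assert at.substituted == frozenset(Metal)
        (uk,) = registry.sets_for(Strategy.NATIONAL, "UK")
        assert uk.substituted == frozenset()


class TestBuildErrors:
    def build(self, tmp_path, rows):
        path = tmp_path / "reg.csv"
        path.write_text("\n".join([REGISTRY_HEADER] + rows) + "\n")
        return build_registry(path)

    def test_duplicate_unconditional_sets(self, tmp_path):
        row = "X1,NATIONAL,FR,none,,,,,,,25,2,150,100,1,50,100,300,"
        with pytest.raises(RegistryError, match="duplicate"):
            self.build(tmp_path, [row, row.replace("X1", "X2")])

    def test_ph_bands_must_partition(self, tmp_path):
        rows = [
            "B1,NATIONAL,XX,ph_band,0,0,6,1,,,25,2,150,100,1,50,100,300,",
            "B2,NATIONAL,XX,ph_band,6.5,0,14,1,,,25,3,150,100,1,50,100,300,",
        ]
        with pytest.raises(RegistryError, match="gap"):
            self.build(tmp_path, rows)

    def test_ph_cut_point_owned_once(self, tmp_path):
        rows = [
            "B1,NATIONAL,XX,ph_band,0,0,6,1,,,25,2,150,100,1,50,100,300,",
            "B2,NATIONAL,XX,ph_band,6,1,14,1,,,25,3,150,100,1,50,100,300,",
        ]
        with pytest.raises(RegistryError, match="cut point"):
            self.build(tmp_path, rows)

    def test_texture_cover_required(self, tmp_path):
        rows = [
            "T1,NATIONAL,XX,texture_category,,,,,poland,light,"
            "25,1,50,25,0.8,20,40,80,",
        ]
        with pytest.raises(RegistryError, match="cover"):
            self.build(tmp_path, rows)

    def test_non_positive_limit(self, tmp_path):
        rows = ["X1,NATIONAL,FR,none,,,,,,,25,0,150,100,1,50,100,300,"]
        with pytest.raises(RegistryError, match="non-positive"):
            self.build(tmp_path, rows)


class TestResolveLimit:
    @pytest.mark.parametrize(
        "ph,metal,expected",
        [
            (7.5, Metal.Zn, 450.0),
            (7.5, Metal.Cd, 4.5),
            (6.0, Metal.Zn, 150.0),   # pH exactly 6 belongs to the acid band
            (6.5, Metal.Ni, 75.0),
            (7.0, Metal.Pb, 300.0),   # pH exactly 7 belongs to the neutral band
            (7.0001, Metal.Pb, 450.0),
        ],
    )
    def test_eu_ph_bands(self, registry, ph, metal, expected):
        s = make_sample(ph_h2o=ph)
        assert resolve_limit(registry, Strategy.EU_PH, s, metal) == expected

    def test_eu_ph_has_no_as_cr(self, registry):
        for ph in (4.0, 6.5, 8.0):
            s = make_sample(ph_h2o=ph)
            assert resolve_limit(registry, Strategy.EU_PH, s, Metal.As) is None
            assert resolve_limit(registry, Strategy.EU_PH, s, Metal.Cr) is None

    def test_uk_arsenic(self, registry):
        s = make_sample(country="UK")
        assert resolve_limit(registry, Strategy.NATIONAL, s, Metal.As) == 50.0

    def test_germany_sand_cadmium(self, registry):
        s = make_sample(country="DE", sand_pct=90.0, silt_pct=5.0, clay_pct=5.0)
        assert resolve_limit(registry, Strategy.NATIONAL, s, Metal.Cd) == 0.4

    def test_poland_texture_bands(self, registry):
        light = make_sample(country="PL", sand_pct=80.0, silt_pct=12.0,
                            clay_pct=8.0)
        heavy = make_sample(country="PL", sand_pct=20.0, silt_pct=35.0,
                            clay_pct=45.0)
        assert resolve_limit(registry, Strategy.NATIONAL, light, Metal.Ni) == 20.0
        assert resolve_limit(registry, Strategy.NATIONAL, heavy, Metal.Ni) == 50.0

    def test_czech_coarse_vs_common(self, registry):
        coarse = make_sample(country="CZ", sand_pct=80.0, silt_pct=12.0,
                             clay_pct=8.0)
        common = make_sample(country="CZ")
        assert resolve_limit(registry, Strategy.NATIONAL, coarse, Metal.Cd) == 4.0
        assert resolve_limit(registry, Strategy.NATIONAL, common, Metal.Cd) == 5.0

    def test_eu_ph_monotone_in_ph(self, registry):
        for metal in (Metal.Cd, Metal.Cu, Metal.Hg, Metal.Ni, Metal.Pb, Metal.Zn):
            limits = [
                resolve_limit(registry, Strategy.EU_PH, make_sample(ph_h2o=ph),
                              metal)
                for ph in np.linspace(0.5, 13.5, 53)
            ]
            assert all(a <= b for a, b in zip(limits, limits[1:]))

    def test_ph_partition_property(self, registry):
        # Exactly one band matches every pH for each pH-banded regime.
        banded = {
            (s.strategy, s.jurisdiction)
            for s in registry.sets
            if s.selector.kind is SelectorKind.ph_band
        }
        assert banded  # the EU regime plus several national ones
        for strategy, jurisdiction in banded:
            sets = registry.sets_for(strategy, jurisdiction)
            for ph in np.arange(0.1, 13.95, 0.05):
                assert sum(s.selector.matches_ph(float(ph)) for s in sets) == 1

    def test_pure_function(self, registry):
        s = make_sample(country="ES", ph_h2o=7.4)
        values = {
            resolve_limit(registry, Strategy.NATIONAL, s, Metal.Cu)
            for _ in range(5)
        }
        assert values == {210.0}

    def test_missing_ph_is_resolution_error(self, registry):
        s = make_sample(country="PT", ph_h2o=None)
        with pytest.raises(ResolutionError, match="pH"):
            resolve_limit(registry, Strategy.NATIONAL, s, Metal.Cd)

    def test_missing_texture_is_resolution_error(self, registry):
        s = make_sample(country="DE", clay_pct=None, silt_pct=None,
                        sand_pct=None)
        with pytest.raises(ResolutionError, match="texture"):
            resolve_limit(registry, Strategy.NATIONAL, s, Metal.Cd)


class TestJurisdiction:
    def test_regional_code_wins(self, registry):
        s = make_sample(country="AT", region_code="AT-steiermark")
        assert jurisdiction_for(registry, s) == "AT-steiermark"
        assert resolve_limit(registry, Strategy.NATIONAL, s, Metal.As) == 20.0

    def test_austria_rest_of_regions_fallback(self, registry):
        s = make_sample(country="AT", region_code=None)
        assert jurisdiction_for(registry, s) == "AT"
        assert resolve_limit(registry, Strategy.NATIONAL, s, Metal.Zn) == 231.0

    def test_single_national_regime(self, registry):
        assert jurisdiction_for(registry, make_sample(country="FR")) == "FR"

    @pytest.mark.parametrize("alias,canonical", [("GR", "EL"), ("GB", "UK")])
    def test_country_aliases(self, registry, alias, canonical):
        s = make_sample(country=alias)
        assert jurisdiction_for(registry, s) == canonical

    def test_unknown_country_names_code(self, registry):
        with pytest.raises(ResolutionError, match="XX"):
            jurisdiction_for(registry, make_sample(country="XX"))

    def test_unknown_region_falls_back_to_country(self, registry):
        s = make_sample(country="AT", region_code="AT-nowhere")
        assert jurisdiction_for(registry, s) == "AT"

    def test_belgium_requires_region(self, registry):
        with pytest.raises(ResolutionError, match="BE"):
            jurisdiction_for(registry, make_sample(country="BE"))
        s = make_sample(country="BE", region_code="BE-flanders")
        assert resolve_limit(registry, Strategy.NATIONAL, s, Metal.Ni) == 18.0


class TestSelectorDescribe:
    def test_describe_forms(self, registry):
        kinds = {s.selector.kind: s.selector.describe() for s in registry.sets}
        assert kinds[SelectorKind.none] == "unconditional"
        assert "pH" in kinds[SelectorKind.ph_band]
        assert ":" in kinds[SelectorKind.texture_category]
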