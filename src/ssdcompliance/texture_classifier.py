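"""USDA texture-triangle classification and national texture category mapping.

The twelve USDA classes are computed from sand/silt/clay mass percentages with
the canonical triangle inequalities.  Germany, Poland, and the Czech Republic
band their soil limit values by texture; the twelve classes collapse onto each
country's categories by general texture group:

====================  =========  ========  ======================================
USDA classes          Germany    Poland    Czech Republic
====================  =========  ========  ======================================
sand, loamy sand      sand       light     sands, clay sands, gravel sands
sandy loam .. silty   loam/silt  medium    common soils
clay loam (7 classes)
sandy clay, silty     clay       heavy     common soils
clay, clay
====================  =========  ========  ======================================
"""

from __future__ import annotations

import enum


class DomainError(ValueError):
    """Texture fractions outside the admissible simplex."""


class UsdaTextureClass(str, enum.Enum):
    sand = "sand"
    loamy_sand = "loamy_sand"
    sandy_loam = "sandy_loam"
    loam = "loam"
    silty_loam = "silty_loam"
    silt = "silt"
    clay_loam = "clay_loam"
    sandy_clay_loam = "sandy_clay_loam"
    silty_clay_loam = "silty_clay_loam"
    sandy_clay = "sandy_clay"
    silty_clay = "silty_clay"
    clay = "clay"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TextureScheme(str, enum.Enum):
    germany = "germany"
    poland = "poland"
    czech = "czech"


#: Category labels per national scheme, ordered coarse -> fine.
SCHEME_CATEGORIES: dict[TextureScheme, tuple[str, ...]] = {
    TextureScheme.germany: ("sand", "loam_silt", "clay"),
    TextureScheme.poland: ("light", "medium", "heavy"),
    TextureScheme.czech: ("sands_claysands_gravelsands", "common_soils"),
}

_COARSE = frozenset({UsdaTextureClass.sand, UsdaTextureClass.loamy_sand})
_FINE = frozenset(
    {UsdaTextureClass.sandy_clay, UsdaTextureClass.silty_clay, UsdaTextureClass.clay}
)

SUM_TOL = 1.0


def classify_usda(
    sand_pct: float, silt_pct: float, clay_pct: float
) -> UsdaTextureClass:
    """Classify a sand/silt/clay composition into one of twelve USDA classes.

    Fractions must each lie in [0, 100] and sum to 100 within 1 percentage
    point; they are renormalised to sum exactly 100 before classification so
    rounded survey data resolve cleanly.  The inequalities are the canonical
    USDA triangle boundaries evaluated in a fixed order, so points on shared
    boundaries resolve deterministically.
    """
    for name, v in (("sand", sand_pct), ("silt", silt_pct), ("clay", clay_pct)):
        if not 0.0 <= v <= 100.0:
            raise DomainError(f"{name} fraction {v} outside [0, 100]")
    total = sand_pct + silt_pct + clay_pct
    if abs(total - 100.0) > SUM_TOL:
        raise DomainError(f"fractions sum to {total:.3f}, not 100 +/- {SUM_TOL}")
    sand = sand_pct * 100.0 / total
    silt = silt_pct * 100.0 / total
    clay = clay_pct * 100.0 / total

    if silt + 1.5 * clay < 15.0:
        return UsdaTextureClass.sand
    if silt + 2.0 * clay < 30.0:
        return UsdaTextureClass.loamy_sand
    if (7.0 <= clay < 20.0 and sand > 52.0) or (clay < 7.0 and silt < 50.0):
        return UsdaTextureClass.sandy_loam
    if 7.0 <= clay < 27.0 and 28.0 <= silt < 50.0 and sand <= 52.0:
        return UsdaTextureClass.loam
    if silt >= 50.0 and ((12.0 <= clay < 27.0) or (silt < 80.0 and clay < 12.0)):
        return UsdaTextureClass.silty_loam
    if silt >= 80.0 and clay < 12.0:
        return UsdaTextureClass.silt
    if 20.0 <= clay < 35.0 and silt < 28.0 and sand > 45.0:
        return UsdaTextureClass.sandy_clay_loam
    if 27.0 <= clay < 40.0 and 20.0 < sand <= 45.0:
        return UsdaTextureClass.clay_loam
    if 27.0 <= clay < 40.0 and sand <= 20.0:
        return UsdaTextureClass.silty_clay_loam
    if clay >= 35.0 and sand > 45.0:
        return UsdaTextureClass.sandy_clay
    if clay >= 40.0 and silt >= 40.0:
        return UsdaTextureClass.silty_clay
    return UsdaTextureClass.clay


def map_national(cls: UsdaTextureClass, scheme: TextureScheme | str) -> str:
    """Collapse a USDA class onto a national texture category.

    Coarse classes (sand, loamy sand) map to the strict category of every
    scheme; fine classes (sandy clay, silty clay, clay) map to Germany's clay
    and Poland's heavy categories; the Czech scheme splits only coarse soils
    from "common soils".
    """
    scheme = TextureScheme(scheme)
    if cls in _COARSE:
        idx = 0
    elif cls in _FINE:
        idx = 2
    else:
        idx = 1
    if scheme is TextureScheme.czech:
        idx = min(idx, 1)
    return SCHEME_CATEGORIES[scheme][idx]
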