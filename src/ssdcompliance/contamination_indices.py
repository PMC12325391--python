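"""Contamination rate indices and one-out-all-out exceedance screening.

The single Contamination Rate Index (CRI) of a metal is its measured
concentration as a percentage of the applicable limit value,

    CRI_i = 100 * C_i / LV_i,

capped at 100 (a capped index marks a sample where no sludge may be spread).
The Overall Contamination Rate Index (OCRI) of a sample is the maximum CRI
across the evaluated metals: under the one-out-all-out principle a site
exceeds the limit values as soon as a single metal does.  Exceedance is
strict (concentration > limit); a concentration exactly at its limit yields
OCRI 100 without exceedance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .limit_registry import LimitRegistry, Strategy, resolve_set
from .sample_model import EIGHT_METALS, METALS, Metal, SoilSample


class ComputationError(ValueError):
    """No metal could be evaluated for a sample."""


@dataclass(frozen=True)
class CriResult:
    """Single contamination rate index of one metal under one strategy."""

    metal: Metal
    strategy: Strategy
    limit_used: float
    cri_raw: float

    @property
    def cri(self) -> float:
        """The capped index, in (0, 100]."""
        return min(self.cri_raw, 100.0)

    @property
    def capped(self) -> bool:
        return self.cri_raw > 100.0

    @property
    def exceeds(self) -> bool:
        return self.cri_raw > 100.0


@dataclass(frozen=True)
class OcriResult:
    """One-out-all-out overall index of one sample under one strategy."""

    sample_id: str
    strategy: Strategy
    ocri: float
    limiting_metal: Metal
    exceeds: bool
    exceeding_metals: frozenset[Metal]
    metals_evaluated: frozenset[Metal]
    cris: Mapping[Metal, CriResult] = field(default_factory=dict, compare=False)


def compute_cri(
    sample: SoilSample,
    strategy: Strategy | str,
    reg: LimitRegistry,
    metal: Metal,
) -> CriResult | None:
    """CRI of one metal, or None when the measurement or the limit is absent.

    Below-LOQ imputation is assumed to have been applied already (it is part
    of sample construction).
    """
    strategy = Strategy(strategy)
    measurement = sample.measurement(metal)
    if measurement is None:
        return None
    limit = resolve_set(reg, strategy, sample).limit(metal)
    if limit is None:
        return None
    return CriResult(
        metal=metal,
        strategy=strategy,
        limit_used=limit,
        cri_raw=100.0 * measurement.effective_value / limit,
    )


def compute_sample_cris(
    sample: SoilSample,
    strategy: Strategy | str,
    reg: LimitRegistry,
    metal_subset: Iterable[Metal] | None = None,
) -> dict[Metal, CriResult]:
    """CRIs for every evaluable metal of a sample, in fixed metal order."""
    metals = EIGHT_METALS if metal_subset is None else tuple(metal_subset)
    out: dict[Metal, CriResult] = {}
    for m in METALS:  # fixed ordering regardless of subset order
        if m in metals:
            r = compute_cri(sample, strategy, reg, m)
            if r is not None:
                out[m] = r
    return out


def compute_ocri(
    sample: SoilSample,
    strategy: Strategy | str,
    reg: LimitRegistry,
    metal_subset: Iterable[Metal] | None = None,
) -> OcriResult:
    """One-out-all-out OCRI over the evaluable metals of a sample.

    For comparisons between the pH-banded EU regime and national regimes pass
    the six-metal subset (Cd, Cu, Hg, Ni, Pb, Zn).  Metals with an absent
    measurement or an absent limit are excluded from the maximum, never
    treated as zero.

    Raises
    ------
    ComputationError
        If no metal in the subset yields an index.
    """
    strategy = Strategy(strategy)
    cris = compute_sample_cris(sample, strategy, reg, metal_subset)
    if not cris:
        raise ComputationError(
            f"{sample.sample_id}: no evaluable metal under strategy {strategy}"
        )
    # Ties in cri_raw break on the fixed Metal ordering (dict preserves it).
    limiting = max(cris, key=lambda m: cris[m].cri_raw)
    exceeding = frozenset(m for m, r in cris.items() if r.exceeds)
    return OcriResult(
        sample_id=sample.sample_id,
        strategy=strategy,
        ocri=max(r.cri for r in cris.values()),
        limiting_metal=limiting,
        exceeds=bool(exceeding),
        exceeding_metals=exceeding,
        metals_evaluated=frozenset(cris),
        cris=cris,
    )


def assess_samples(
    samples: Sequence[SoilSample],
    strategy: Strategy | str,
    reg: LimitRegistry,
    metal_subset: Iterable[Metal] | None = None,
) -> list[OcriResult]:
    """Per-sample OCRI results, preserving input order."""
    return [compute_ocri(s, strategy, reg, metal_subset) for s in samples]


def results_frame(results: Sequence[OcriResult]) -> pd.DataFrame:
    """Tabular view of OCRI results: one row per sample.

    Columns: sample_id, strategy, cri_<metal> (capped) for all eight metals,
    ocri, limiting_metal, exceeds, exceeding_metals (semicolon list).
    """
    rows = []
    for r in results:
        row: dict[str, object] = {"sample_id": r.sample_id, "strategy": r.strategy.value}
        for m in METALS:
            cri = r.cris.get(m)
            row[f"cri_{m.value}"] = None if cri is None else cri.cri
        row["ocri"] = r.ocri
        row["limiting_metal"] = r.limiting_metal.value
        row["exceeds"] = r.exceeds
        row["exceeding_metals"] = ";".join(
            m.value for m in METALS if m in r.exceeding_metals
        )
        rows.append(row)
    columns = (
        ["sample_id", "strategy"]
        + [f"cri_{m.value}" for m in METALS]
        + ["ocri", "limiting_metal", "exceeds", "exceeding_metals"]
    )
    return pd.DataFrame(rows, columns=columns)


def exceedance_table(
    samples: Sequence[SoilSample],
    strategy: Strategy | str,
    reg: LimitRegistry,
    metal_subset: Iterable[Metal] | None = None,
) -> pd.DataFrame:
    """Per-metal and overall exceedance proportions across a sample set.

    One row per metal plus an ``overall`` row; the denominator of each metal
    row counts only the samples where that metal was evaluable.
    """
    if not samples:
        raise ComputationError("empty sample set")
    strategy = Strategy(strategy)
    metals = EIGHT_METALS if metal_subset is None else tuple(metal_subset)
    counts = {m: [0, 0] for m in METALS if m in metals}  # metal -> [evaluable, exceed]
    overall = [0, 0]
    for s in samples:
        cris = compute_sample_cris(s, strategy, reg, metals)
        if cris:
            overall[0] += 1
            if any(r.exceeds for r in cris.values()):
                overall[1] += 1
        for m, r in cris.items():
            counts[m][0] += 1
            counts[m][1] += r.exceeds
    rows = []
    for m, (n, k) in counts.items():
        rows.append(
            {
                "metal": m.value,
                "n_evaluable": n,
                "n_exceeding": k,
                "exceedance_pct": (100.0 * k / n) if n else float("nan"),
            }
        )
    rows.append(
        {
            "metal": "overall",
            "n_evaluable": overall[0],
            "n_exceeding": overall[1],
            "exceedance_pct": (
                100.0 * overall[1] / overall[0] if overall[0] else float("nan")
            ),
        }
    )
    return pd.DataFrame(rows)
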