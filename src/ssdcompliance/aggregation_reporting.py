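"""Regional aggregation of per-sample indices and report emission.

Per-sample overall indices are aggregated to country (NUTS0) and region
(NUTS2) level as arithmetic means of the capped values, with sample standard
deviations (n-1 denominator; absent for single-sample regions) and exceedance
proportions.  NUTS codes are opaque strings; no geometry is involved.
"""

from __future__ import annotations

import enum
import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .compliance_assessment import ComplianceResult, compliance_frame
from .contamination_indices import OcriResult
from .sample_model import SoilSample

logger = logging.getLogger(__name__)


class Level(str, enum.Enum):
    nuts0 = "nuts0"
    nuts2 = "nuts2"


@dataclass(frozen=True)
class AggregateSummary:
    """Grouped OCRI statistics for one region at one level."""

    level: Level
    code: str
    strategy: str
    n: int
    mean_ocri: float
    sd_ocri: float | None
    exceedance_pct: float


def _code_for(sample: SoilSample, level: Level) -> str | None:
    if level is Level.nuts0:
        return sample.country or None
    return sample.nuts2


def aggregate(
    results: Sequence[OcriResult],
    samples: Sequence[SoilSample],
    level: Level | str,
) -> list[AggregateSummary]:
    """Aggregate OCRI results by region code, ordered by code.

    Samples lacking a code for the requested level are logged and excluded
    from that level only.
    """
    level = Level(level)
    by_id = {s.sample_id: s for s in samples}
    groups: dict[tuple[str, str], list[OcriResult]] = {}
    skipped = 0
    for r in results:
        sample = by_id.get(r.sample_id)
        code = _code_for(sample, level) if sample is not None else None
        if code is None:
            skipped += 1
            continue
        groups.setdefault((code, r.strategy.value), []).append(r)
    if skipped:
        logger.warning(
            "aggregate(%s): %d result(s) without a %s code excluded",
            level.value,
            skipped,
            level.value,
        )
    out = []
    for (code, strategy), rs in sorted(groups.items()):
        values = [r.ocri for r in rs]
        out.append(
            AggregateSummary(
                level=level,
                code=code,
                strategy=strategy,
                n=len(values),
                mean_ocri=statistics.fmean(values),
                sd_ocri=statistics.stdev(values) if len(values) > 1 else None,
                exceedance_pct=100.0 * sum(r.exceeds for r in rs) / len(rs),
            )
        )
    return out


def summaries_frame(summaries: Sequence[AggregateSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "level": s.level.value,
                "code": s.code,
                "strategy": s.strategy,
                "n": s.n,
                "mean_ocri": s.mean_ocri,
                "sd_ocri": s.sd_ocri,
                "exceedance_pct": s.exceedance_pct,
            }
            for s in summaries
        ],
        columns=[
            "level",
            "code",
            "strategy",
            "n",
            "mean_ocri",
            "sd_ocri",
            "exceedance_pct",
        ],
    )


def _country_table(summaries: Sequence[AggregateSummary]) -> pd.DataFrame:
    """Country table with one mean(SD) column pair per strategy present."""
    frame = summaries_frame(summaries)
    if frame.empty:
        return frame
    table = frame.pivot_table(
        index="code", columns="strategy", values=["n", "mean_ocri", "sd_ocri"]
    )
    rows = []
    for code in sorted(frame["code"].unique()):
        row: dict[str, object] = {"code": code}
        for strategy in sorted(frame["strategy"].unique()):
            sub = frame[(frame["code"] == code) & (frame["strategy"] == strategy)]
            if sub.empty:
                continue
            rec = sub.iloc[0]
            row["n"] = int(rec["n"])
            sd = "-" if pd.isna(rec["sd_ocri"]) else f"({rec['sd_ocri']:.1f})"
            row[f"ocri_{strategy.lower()}"] = f"{rec['mean_ocri']:.1f}{sd}"
        rows.append(row)
    del table
    return pd.DataFrame(rows)


def write_report(
    summaries: Sequence[AggregateSummary],
    compliance: Sequence[ComplianceResult] | None,
    path: str | Path,
    samples: Sequence[SoilSample] | None = None,
) -> dict[str, Path]:
    """Write machine-readable CSVs plus a human-readable text report.

    Emits ``nuts0_summary.csv`` / ``nuts2_summary.csv`` for the levels present
    in ``summaries``, ``compliance_by_country.csv`` when compliance results
    and samples are given (per-sample ratios averaged per country), and
    ``report.txt``.  Returns the written paths keyed by artefact name.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    frame = summaries_frame(summaries)
    text_sections: list[str] = []
    for level in Level:
        sub = frame[frame["level"] == level.value].drop(columns=["level"])
        if sub.empty:
            continue
        target = outdir / f"{level.value}_summary.csv"
        sub.to_csv(target, index=False)
        written[f"{level.value}_summary"] = target
        if level is Level.nuts0:
            table = _country_table(
                [s for s in summaries if s.level is Level.nuts0]
            )
            text_sections.append(
                "Arithmetic average of OCRI values (%) at NUTS0 level\n"
                + table.to_string(index=False)
            )
    if compliance:
        cframe = compliance_frame(compliance)
        if samples is not None:
            country = {s.sample_id: s.country for s in samples}
            cframe.insert(1, "country", cframe["sample_id"].map(country))
            by_country = (
                cframe.groupby("country")
                .agg(n=("ratio", "size"), mean_ratio=("ratio", "mean"))
                .reset_index()
            )
            from .compliance_assessment import categorize_ratio

            by_country["category"] = by_country["mean_ratio"].map(
                lambda r: categorize_ratio(r).value
            )
            target = outdir / "compliance_by_country.csv"
            by_country.to_csv(target, index=False)
            written["compliance_by_country"] = target
            text_sections.append(
                "Compliance grade (mean OCRI_Nat/OCRI_EU ratio) by country\n"
                + by_country.to_string(index=False)
            )
        target = outdir / "compliance_per_sample.csv"
        cframe.to_csv(target, index=False)
        written["compliance_per_sample"] = target
    else:
        logger.warning("write_report: no compliance results; section omitted")
    report = outdir / "report.txt"
    report.write_text("\n\n".join(text_sections) + "\n")
    written["report"] = report
    return written
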