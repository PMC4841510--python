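"""Link PAF estimates to disease-specific death counts.

Multiplying a disease's death count by its PAF gives the deaths
attributable to genetics plus shared exposures; summing over diseases and
dividing by total deaths gives an overall attributable percentage, which is
the death-weighted mean of the matched PAFs and therefore always lies
between the smallest and largest of them.

The package ships an *illustrative, synthetic* mortality table
(``data/synthetic_mortality.csv``) whose death counts are invented round
numbers on a realistic scale; real analyses should supply actual
burden-of-disease mortality counts in the same CSV schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import LinkageError, TableFormatError, ValidationError
from .estimator import ConcordanceEstimate

__all__ = [
    "MortalityRecord",
    "AttributionResult",
    "LinkedAttribution",
    "attributable_deaths",
    "read_mortality_table",
    "bundled_synthetic_mortality",
    "link",
    "attribution_to_frame",
]

MORTALITY_FIELDS = ("disease_name", "region", "year", "deaths")


@dataclass(frozen=True)
class MortalityRecord:
    """Death count for one disease, region and calendar year."""

    disease_name: str
    region: str
    year: int
    deaths: float

    def __post_init__(self) -> None:
        if self.deaths < 0:
            raise ValidationError(
                f"{self.disease_name!r}: deaths must be non-negative, got {self.deaths}"
            )


@dataclass(frozen=True)
class AttributionResult:
    disease_name: str
    deaths: float
    paf_pct: float
    attributable_deaths: float


@dataclass(frozen=True)
class LinkedAttribution:
    """Per-disease attributable deaths plus totals."""

    results: tuple[AttributionResult, ...]
    total_deaths: float
    total_attributable: float
    overall_attributable_pct: float


def attributable_deaths(deaths: float, paf_pct: float) -> float:
    """deaths x PAF/100, unrounded."""
    if deaths < 0:
        raise ValidationError(f"deaths must be non-negative, got {deaths}")
    if not 0.0 <= paf_pct <= 100.0:
        raise ValidationError(f"paf_pct must lie in [0, 100], got {paf_pct}")
    return deaths * paf_pct / 100.0


def read_mortality_table(path: str | Path) -> list[MortalityRecord]:
    """Read a UTF-8 CSV with columns disease_name, region, year, deaths."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in MORTALITY_FIELDS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"missing column(s): {', '.join(missing)}")
    if frame.empty:
        raise ValidationError(f"empty mortality table: {path}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                MortalityRecord(
                    disease_name=row.disease_name,
                    region=row.region,
                    year=int(row.year),
                    deaths=float(row.deaths),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def bundled_synthetic_mortality() -> list[MortalityRecord]:
    """The packaged synthetic mortality table (invented illustrative counts)."""
    source = resources.files("twinpaf.data").joinpath("synthetic_mortality.csv")
    with resources.as_file(source) as path:
        return read_mortality_table(path)


def link(
    estimates: Iterable[ConcordanceEstimate],
    mortality: Sequence[MortalityRecord],
    aliases: Optional[Mapping[str, str]] = None,
) -> LinkedAttribution:
    """Match mortality records to estimates by disease name and attribute deaths.

    Matching is exact-string on ``disease_name`` after applying the optional
    ``aliases`` map (mortality-table name -> estimate name). Every mortality
    record must match exactly one estimate; unmatched or ambiguous names
    raise :class:`LinkageError`.
    """
    aliases = dict(aliases or {})
    by_name: dict[str, list[ConcordanceEstimate]] = {}
    for e in estimates:
        if e.source is None:
            raise ValidationError("link needs estimates carrying their source record")
        by_name.setdefault(e.source.disease_name, []).append(e)

    results = []
    unmatched = []
    for m in mortality:
        name = aliases.get(m.disease_name, m.disease_name)
        matches = by_name.get(name, [])
        if not matches:
            unmatched.append(m.disease_name)
            continue
        if len(matches) > 1:
            raise LinkageError(
                f"{m.disease_name!r} matches {len(matches)} estimates named {name!r}"
            )
        est = matches[0]
        results.append(
            AttributionResult(
                disease_name=name,
                deaths=m.deaths,
                paf_pct=est.paf_pct,
                attributable_deaths=attributable_deaths(m.deaths, est.paf_pct),
            )
        )
    if unmatched:
        raise LinkageError(f"no estimate matches mortality record(s): {unmatched}")
    total = sum(r.deaths for r in results)
    attributable = sum(r.attributable_deaths for r in results)
    if total == 0:
        raise ValidationError("total deaths are zero; overall percentage undefined")
    return LinkedAttribution(
        results=tuple(results),
        total_deaths=total,
        total_attributable=attributable,
        overall_attributable_pct=100.0 * attributable / total,
    )


def attribution_to_frame(linked: LinkedAttribution) -> pd.DataFrame:
    """Per-disease rows plus a TOTAL row, for CSV export."""
    rows = [
        {
            "disease_name": r.disease_name,
            "deaths": r.deaths,
            "paf_pct": r.paf_pct,
            "attributable_deaths": r.attributable_deaths,
        }
        for r in linked.results
    ]
    rows.append(
        {
            "disease_name": "TOTAL",
            "deaths": linked.total_deaths,
            "paf_pct": linked.overall_attributable_pct,
            "attributable_deaths": linked.total_attributable,
        }
    )
    return pd.DataFrame(rows, columns=["disease_name", "deaths", "paf_pct", "attributable_deaths"])
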