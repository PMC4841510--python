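"""Cohort-level summaries of PAF estimates.

Two empirical quantile conventions are provided because published summary
numbers for this kind of table mix them: ``inverse_ecdf`` (the smallest
sample value whose empirical CDF reaches q — always a member of the sample)
and ``midpoint`` (which averages the two central order statistics for the
median of an even-sized sample and otherwise behaves like ``inverse_ecdf``).
For the bundled 28-phenotype table the overall median and quartiles follow
the inverse-ECDF convention while the per-category medians follow the
midpoint convention; both are user-selectable and the defaults reproduce the
published summary numbers. For odd sample sizes the two conventions agree at
the median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .estimator import ConcordanceEstimate, round_sig

__all__ = [
    "CONVENTIONS",
    "quantile",
    "SummaryReport",
    "summarize",
    "cumulative_distribution",
    "report_to_frame",
    "format_report",
]

CONVENTIONS = ("inverse_ecdf", "midpoint")


def quantile(values: Sequence[float], q: float, convention: str = "inverse_ecdf") -> float:
    """Empirical quantile of ``values`` at probability ``q``."""
    xs = sorted(values)
    n = len(xs)
    if n == 0:
        raise ValidationError("quantile of an empty sample is undefined")
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"q must lie in [0, 1], got {q}")
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown convention {convention!r}; expected {CONVENTIONS}")
    if convention == "midpoint" and q == 0.5 and n % 2 == 0:
        return (xs[n // 2 - 1] + xs[n // 2]) / 2.0
    # smallest order statistic whose ECDF (i+1)/n reaches q
    index = max(math.ceil(q * n), 1) - 1
    return xs[index]


@dataclass(frozen=True)
class SummaryReport:
    """Range, median, IQR and per-category medians of a set of PAF estimates."""

    n_diseases: int
    min_paf: float
    min_disease: str
    max_paf: float
    max_disease: str
    median_paf: float
    iqr: tuple[float, float]
    category_medians: dict[str, float] = field(default_factory=dict)
    convention_overall: str = "inverse_ecdf"
    convention_category: str = "midpoint"


def _require_sources(estimates: Sequence[ConcordanceEstimate]) -> None:
    if any(e.source is None for e in estimates):
        raise ValidationError("summaries need estimates carrying their source record")


def summarize(
    estimates: Iterable[ConcordanceEstimate],
    convention_overall: str = "inverse_ecdf",
    convention_category: str = "midpoint",
) -> SummaryReport:
    """Summarise PAFs across diseases.

    Works on full-precision PAFs; round for display with
    :func:`twinpaf.estimator.round_sig`.
    """
    ests = list(estimates)
    if not ests:
        raise ValidationError("summarize requires at least one estimate")
    _require_sources(ests)
    pafs = [e.paf_pct for e in ests]
    lo = min(ests, key=lambda e: e.paf_pct)
    hi = max(ests, key=lambda e: e.paf_pct)
    by_category: dict[str, list[float]] = {}
    for e in ests:
        by_category.setdefault(e.source.category, []).append(e.paf_pct)
    return SummaryReport(
        n_diseases=len(ests),
        min_paf=lo.paf_pct,
        min_disease=lo.source.disease_name,
        max_paf=hi.paf_pct,
        max_disease=hi.source.disease_name,
        median_paf=quantile(pafs, 0.5, convention_overall),
        iqr=(
            quantile(pafs, 0.25, convention_overall),
            quantile(pafs, 0.75, convention_overall),
        ),
        category_medians={
            cat: quantile(vals, 0.5, convention_category)
            for cat, vals in sorted(by_category.items())
        },
        convention_overall=convention_overall,
        convention_category=convention_category,
    )


def cumulative_distribution(
    estimates: Iterable[ConcordanceEstimate],
) -> pd.DataFrame:
    """Empirical cumulative distribution of PAFs, one point per disease.

    Returns a frame sorted ascending by PAF with columns ``disease_name``,
    ``category``, ``paf_pct`` and ``cumulative_fraction`` ((i+1)/n); tied
    PAFs are kept as separate points with distinct cumulative fractions.
    """
    ests = list(estimates)
    if not ests:
        raise ValidationError("cumulative_distribution requires at least one estimate")
    _require_sources(ests)
    ests.sort(key=lambda e: (e.paf_pct, e.source.disease_name))
    n = len(ests)
    return pd.DataFrame(
        {
            "disease_name": [e.source.disease_name for e in ests],
            "category": [e.source.category for e in ests],
            "paf_pct": [e.paf_pct for e in ests],
            "cumulative_fraction": [(i + 1) / n for i in range(n)],
        }
    )


def report_to_frame(report: SummaryReport) -> pd.DataFrame:
    """One row per summary statistic, for CSV export."""
    rows = [
        ("n_diseases", report.n_diseases, ""),
        ("min_paf_pct", report.min_paf, report.min_disease),
        ("max_paf_pct", report.max_paf, report.max_disease),
        ("median_paf_pct", report.median_paf, report.convention_overall),
        ("iqr_lower_pct", report.iqr[0], report.convention_overall),
        ("iqr_upper_pct", report.iqr[1], report.convention_overall),
    ]
    rows += [
        (f"median_paf_pct[{cat}]", value, report.convention_category)
        for cat, value in report.category_medians.items()
    ]
    return pd.DataFrame(rows, columns=["statistic", "value", "detail"])


def format_report(report: SummaryReport) -> str:
    """Plain-text paragraph mirroring how such results are usually reported."""
    cats = ", ".join(
        f"{cat} {round_sig(v):g}%" for cat, v in report.category_medians.items()
    )
    return (
        f"PAFs for {report.n_diseases} diseases ranged from "
        f"{round_sig(report.min_paf):g}% ({report.min_disease}) to "
        f"{round_sig(report.max_paf):g}% ({report.max_disease}), with a median of "
        f"{round_sig(report.median_paf):g}% and an interquartile range of "
        f"{round_sig(report.iqr[0], 2):g}% to {round_sig(report.iqr[1]):g}%. "
        f"Category medians: {cats}."
    )
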