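"""Probandwise concordance, co-twin relative risk, and the case-based PAF.

Given MZ pair counts (N_T total, N_C concordant, N_D discordant), the
estimator views the 2·N_T individual twins as a 2x2 co-twin exposure table:

* "exposed" twins have an affected co-twin: 2·N_C + N_D individuals, of whom
  the 2·N_C in concordant pairs are affected;
* "unexposed" twins have an unaffected co-twin: 2·N_T − 2·N_C − N_D
  individuals, of whom the N_D affected members of discordant pairs are
  affected.

From this table,

    P   = 2·N_C / (2·N_C + N_D) × 100        (probandwise concordance, %)
    RR  = [2·N_C/(2·N_C+N_D)] / [N_D/(2·N_T−2·N_C−N_D)]
    PAF = P · (RR − 1) / RR                  (attributable fraction among
                                              cases, Miettinen's case-based
                                              form, in %)

Because MZ co-twins share their genome and many early-life exposures, PAF
here measures the case fraction attributable to genotype *plus shared
exposures*, not to genes alone.

Degenerate conventions (continuous limits of the formulas): P = 0 gives
PAF = 0; N_D = 0 with N_C > 0 gives RR = +inf and PAF = P.  RR < 1 (possible
on user data) yields a negative PAF which is returned as computed but
flagged. All statistics are kept in full floating precision; rounding to the
3 significant figures conventional for reporting happens only in
:func:`round_sig` / presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import UndefinedStatisticError, ValidationError
from .records import TwinCohortRecord

__all__ = [
    "ConcordanceEstimate",
    "probandwise_concordance",
    "relative_risk",
    "population_attributable_fraction",
    "estimate",
    "bootstrap_interval",
    "round_sig",
]


@dataclass(frozen=True)
class ConcordanceEstimate:
    """Derived statistics for one twin-cohort record.

    ``risk_cotwin_affected`` and ``risk_cotwin_unaffected`` are the two
    risks whose ratio is ``relative_risk``; ``probandwise_concordance_pct``
    is 100 times the former.  ``rr_below_one`` flags the out-of-model case
    RR < 1, in which ``paf_pct`` is negative.
    """

    probandwise_concordance_pct: float
    risk_cotwin_affected: float
    risk_cotwin_unaffected: float
    relative_risk: float  # math.inf when N_D = 0 and N_C > 0
    paf_pct: float
    rr_below_one: bool = False
    source: Optional[TwinCohortRecord] = None


def _check_counts(n_pairs_total: int, n_concordant: int, n_discordant: int) -> None:
    if min(n_pairs_total, n_concordant, n_discordant) < 0:
        raise ValidationError("counts must be non-negative")
    if n_concordant + n_discordant > n_pairs_total:
        raise ValidationError("n_concordant + n_discordant exceeds n_pairs_total")


def probandwise_concordance(n_concordant: int, n_discordant: int) -> float:
    """Percent of affected twins whose co-twin is also affected.

    Each concordant pair contributes two affected individuals, both with an
    affected co-twin; each discordant pair contributes one affected
    individual whose co-twin is unaffected.
    """
    affected = 2 * n_concordant + n_discordant
    if affected < 1:
        raise UndefinedStatisticError(
            "probandwise concordance undefined: no affected individuals"
        )
    return 2 * n_concordant / affected * 100.0


def relative_risk(
    n_pairs_total: int, n_concordant: int, n_discordant: int
) -> float:
    """Risk of disease given an affected co-twin over risk given an unaffected one.

    Returns ``math.inf`` when no discordant pairs exist but concordant ones do
    (the unexposed risk is exactly zero). Raises
    :class:`UndefinedStatisticError` when there are no affected individuals or
    when every twin has an affected co-twin (N_T = N_C, N_D = 0), which leaves
    the unexposed group empty.
    """
    _check_counts(n_pairs_total, n_concordant, n_discordant)
    exposed_n = 2 * n_concordant + n_discordant
    if exposed_n < 1:
        raise UndefinedStatisticError("relative risk undefined: no affected individuals")
    unexposed_n = 2 * n_pairs_total - 2 * n_concordant - n_discordant
    if unexposed_n == 0:
        raise UndefinedStatisticError(
            "relative risk undefined: every twin has an affected co-twin"
        )
    risk_exposed = 2 * n_concordant / exposed_n
    risk_unexposed = n_discordant / unexposed_n
    if risk_unexposed == 0.0:
        return math.inf
    return risk_exposed / risk_unexposed


def population_attributable_fraction(
    n_pairs_total: int, n_concordant: int, n_discordant: int
) -> float:
    """PAF (%) = P · (RR − 1)/RR, with the degenerate conventions above."""
    p = probandwise_concordance(n_concordant, n_discordant)
    if p == 0.0:
        return 0.0
    rr = relative_risk(n_pairs_total, n_concordant, n_discordant)
    if math.isinf(rr):
        return p
    return p * (rr - 1.0) / rr


def estimate(record: TwinCohortRecord) -> ConcordanceEstimate:
    """Compute P, RR and PAF for one record, with intermediate risks."""
    nt, nc, nd = record.n_pairs_total, record.n_concordant, record.n_discordant
    p = probandwise_concordance(nc, nd)
    if nc == 0:
        # P = 0: risks still well defined unless the table is degenerate
        rr = relative_risk(nt, nc, nd)
        paf = 0.0
    else:
        rr = relative_risk(nt, nc, nd)
        paf = p if math.isinf(rr) else p * (rr - 1.0) / rr
    unexposed_n = 2 * nt - 2 * nc - nd
    return ConcordanceEstimate(
        probandwise_concordance_pct=p,
        risk_cotwin_affected=p / 100.0,
        risk_cotwin_unaffected=(nd / unexposed_n) if unexposed_n else math.nan,
        relative_risk=rr,
        paf_pct=paf,
        rr_below_one=rr < 1.0,
        source=record,
    )


_STATISTICS = {
    "P": lambda nt, nc, nd: probandwise_concordance(nc, nd),
    "RR": relative_risk,
    "PAF": population_attributable_fraction,
}


def bootstrap_interval(
    record: TwinCohortRecord,
    statistic: str = "PAF",
    n_resamples: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile 95% bootstrap interval for P, RR or PAF.

    Pairs are the sampling unit: each resample draws N_T pairs from the
    multinomial with cell probabilities (N_C, N_D, N_T−N_C−N_D)/N_T and
    recomputes the statistic, skipping resamples on which it is undefined.
    Returns the 2.5 and 97.5 percentiles; reproducible for a fixed seed.
    """
    if statistic not in _STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}; expected P, RR or PAF")
    if n_resamples < 1:
        raise ValidationError("n_resamples must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nt = record.n_pairs_total
    probs = np.array(
        [record.n_concordant, record.n_discordant, record.n_unaffected_pairs],
        dtype=float,
    ) / nt
    draws = rng.multinomial(nt, probs, size=n_resamples)
    func = _STATISTICS[statistic]
    values = []
    for nc, nd, _ in draws:
        try:
            values.append(func(nt, int(nc), int(nd)))
        except UndefinedStatisticError:
            continue
    if not values:
        raise UndefinedStatisticError(
            f"{statistic} undefined on all {n_resamples} bootstrap resamples"
        )
    lower, upper = np.percentile(values, [2.5, 97.5])
    return float(lower), float(upper)


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (banker's rounding, as Python's
    ``round``); 0 and non-finite values pass through unchanged."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - math.floor(math.log10(abs(x))))
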