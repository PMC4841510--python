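"""Synthetic MZ-twin cohorts for estimator validation.

A cohort of N twin pairs is summarised by a three-category multinomial over
pair outcomes: both twins affected (probability ``p_both``), exactly one
affected (``p_one``), neither (``p_neither``). Any such triple can be
injected directly; as a convenient generator the classical
liability-threshold model is provided: each pair carries a standard
bivariate-normal latent liability with within-pair correlation r, and a twin
is affected when its liability exceeds the threshold Phi^-1(1-K) set by the
lifetime prevalence K. Then

    p_both    = P(X > t, Y > t)   (upper orthant of the bivariate normal)
    p_one     = 2 (K - p_both)
    p_neither = 1 - p_both - p_one

r = 0 gives independent twins (p_both = K^2, true RR = 1, true PAF = 0);
r = 1 gives comonotone liabilities (p_both = K, no discordant pairs, true
PAF = 100 under the RR -> inf convention). The true (population) P, RR and
PAF of a generating triple are the count formulas applied to expected
proportions, enabling parameter-recovery tests of the estimator.

No exposure covariates are simulated: like the twin registries the analysis
targets, the generator cannot separate genetics from shared environment, so
its "true PAF" deliberately conflates the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .errors import UndefinedStatisticError, ValidationError
from .estimator import ConcordanceEstimate
from .records import TwinCohortRecord

__all__ = [
    "PairOutcomeProbabilities",
    "LiabilityModelSpec",
    "pair_probs_from_liability",
    "true_statistics",
    "simulate_cohort",
    "paf_standard_error",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class PairOutcomeProbabilities:
    """Multinomial cell probabilities for one twin pair's outcome."""

    p_both: float
    p_one: float
    p_neither: float

    def __post_init__(self) -> None:
        for name in ("p_both", "p_one", "p_neither"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {p}")
        total = self.p_both + self.p_one + self.p_neither
        if abs(total - 1.0) > _SUM_TOL:
            raise ValidationError(f"probabilities must sum to 1, got {total!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_both, self.p_one, self.p_neither])


@dataclass(frozen=True)
class LiabilityModelSpec:
    """Prevalence K and within-pair liability correlation r."""

    prevalence: float
    liability_correlation: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError(
                f"prevalence must lie strictly in (0, 1), got {self.prevalence}"
            )
        if not 0.0 <= self.liability_correlation <= 1.0:
            raise ValidationError(
                f"liability_correlation must lie in [0, 1], got {self.liability_correlation}"
            )

    @property
    def threshold(self) -> float:
        """Liability threshold: the (1 - K) standard-normal quantile."""
        return float(stats.norm.ppf(1.0 - self.prevalence))


def _orthant_probability(threshold: float, r: float) -> float:
    """P(X > t, Y > t) for standard bivariate normal with correlation r.

    Evaluated as the 1-D integral of phi(x) * Phi-bar((t - r x)/sqrt(1-r^2))
    over x > t; adaptive quadrature holds the absolute error well below 1e-8.
    r = 0 and r = 1 are exact special cases (K^2 and K).
    """
    k = float(stats.norm.sf(threshold))
    if r == 0.0:
        return k * k
    if r == 1.0:
        return k
    scale = math.sqrt(1.0 - r * r)

    def integrand(x: float) -> float:
        return stats.norm.pdf(x) * stats.norm.sf((threshold - r * x) / scale)

    value, _ = integrate.quad(integrand, threshold, np.inf, epsabs=1e-10, limit=200)
    return float(value)


def pair_probs_from_liability(spec: LiabilityModelSpec) -> PairOutcomeProbabilities:
    """Pair-outcome probabilities implied by a liability-threshold model."""
    k = spec.prevalence
    p_both = _orthant_probability(spec.threshold, spec.liability_correlation)
    p_both = min(p_both, k)  # guard quadrature round-off at r near 1
    p_one = 2.0 * (k - p_both)
    return PairOutcomeProbabilities(
        p_both=p_both, p_one=p_one, p_neither=1.0 - p_both - p_one
    )


def true_statistics(probs: PairOutcomeProbabilities) -> ConcordanceEstimate:
    """Analytic P, RR and PAF of the generating model.

    These are the count-based formulas applied to population proportions:
    P = 2 p_both/(2 p_both + p_one) x 100, unexposed risk
    p_one/(p_one + 2 p_neither), with the same degenerate conventions as the
    estimator (p_one = 0 gives RR = inf and PAF = P; p_both = 0 gives
    PAF = 0).
    """
    pb, po, pn = probs.p_both, probs.p_one, probs.p_neither
    if pb + po == 0.0:
        raise UndefinedStatisticError("no affected mass: statistics undefined")
    p = 2.0 * pb / (2.0 * pb + po) * 100.0
    risk_exposed = p / 100.0
    unexposed_mass = po + 2.0 * pn
    risk_unexposed = po / unexposed_mass if unexposed_mass > 0 else math.nan
    if po == 0.0:
        rr: float = math.inf
        paf = p
    elif pb == 0.0:
        rr = 0.0
        paf = 0.0
    else:
        rr = risk_exposed / risk_unexposed
        paf = p * (rr - 1.0) / rr
    return ConcordanceEstimate(
        probandwise_concordance_pct=p,
        risk_cotwin_affected=risk_exposed,
        risk_cotwin_unaffected=risk_unexposed,
        relative_risk=rr,
        paf_pct=paf,
        rr_below_one=rr < 1.0,
        source=None,
    )


def simulate_cohort(
    probs: PairOutcomeProbabilities,
    n_pairs: int,
    seed: int | np.random.Generator = 0,
    disease_name: str = "simulated disease",
    category: str = "other",
    country: str = "synthetic",
    sex_subset: str = "both",
) -> TwinCohortRecord:
    """Draw (N_C, N_D, N_neither) ~ Multinomial(n_pairs, probs) as a record."""
    if n_pairs < 1:
        raise ValidationError("n_pairs must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nc, nd, _ = rng.multinomial(n_pairs, probs.as_array())
    return TwinCohortRecord(
        disease_name=disease_name,
        category=category,
        country=country,
        sex_subset=sex_subset,
        n_pairs_total=n_pairs,
        n_concordant=int(nc),
        n_discordant=int(nd),
    )


def paf_standard_error(probs: PairOutcomeProbabilities, n_pairs: int) -> float:
    """Delta-method Monte-Carlo SE of the PAF estimated from one cohort.

    Propagates the multinomial covariance of the cell proportions through the
    PAF formula by numerical differentiation. Used to scale recovery
    tolerances; returns the SE in percentage points.
    """

    def paf_of(p: np.ndarray) -> float:
        pb, po, pn = p
        if pb + po <= 0:
            return 0.0
        pct = 2 * pb / (2 * pb + po) * 100.0
        if po == 0:
            return pct
        rr = (pct / 100.0) / (po / (po + 2 * pn))
        return pct * (rr - 1.0) / rr if rr > 0 else 0.0

    p = probs.as_array()
    cov = (np.diag(p) - np.outer(p, p)) / n_pairs
    eps = 1e-6
    base = paf_of(p)
    grad = np.zeros(3)
    for i in range(3):
        q = p.copy()
        q[i] += eps
        q /= q.sum()
        grad[i] = (paf_of(q) - base) / eps
    return float(np.sqrt(grad @ cov @ grad))
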