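# Methods

## Model and estimands

A monozygotic (MZ) twin cohort for one disease is summarised by three pair
counts: `N_T` pairs total, `N_C` concordant (both affected), `N_D`
discordant (exactly one affected). The 2·N_T individual twins are laid out
as a 2×2 table in which a twin's "exposure" is having an affected co-twin:

|                       | affected | total            |
|-----------------------|----------|------------------|
| co-twin affected      | 2·N_C    | 2·N_C + N_D      |
| co-twin unaffected    | N_D      | 2·N_T − 2·N_C − N_D |

Probandwise concordance `P = 2N_C/(2N_C+N_D)×100` is the affected-twin risk
of the exposed row; the co-twin relative risk RR is the ratio of the two
row risks; and the population attributable fraction follows Miettinen's
case-based form `PAF = P(RR−1)/RR`, interpreted as the percentage of cases
that would not occur if the "exposure" — here the combination of genotype
and the environment shared within a pair — were absent. Because MZ twins
share both, the estimand deliberately conflates genetics with shared
exposures; nothing in pair counts can separate them, nor identify
non-shared-exposure or gene–environment-interaction contributions.

Assumptions: pairs are independent and identically distributed within a
cohort, and a cohort's pair outcome is a three-category multinomial
(both / one / neither affected). Rows of a multi-disease table are treated
as independent even where registries overlap, since cross-disease
dependence is unidentifiable from the published counts.

## Degenerate-input conventions

All conventions are continuous limits of the formulas:

- no affected individuals (`2N_C+N_D = 0`): P, RR, PAF undefined → error;
- `N_C = 0`: P = 0 and PAF = 0 (avoids 0/0 in `P(RR−1)/RR`);
- `N_D = 0` with `0 < N_C < N_T`: unexposed risk 0, RR = +∞, PAF = P;
- `N_C = N_T` (no unexposed twins): RR undefined → error;
- RR < 1 (possible on user data, never in the bundled table): PAF is
  returned negative as computed, with a `rr_below_one` flag rather than
  clamping.

Statistics are computed in full floating precision; rounding to 3
significant figures (Python's banker's rounding) happens only at
presentation.

## Quantile conventions

Two empirical quantile conventions are implemented because the published
summary numbers for the bundled table mix them: `inverse_ecdf` (smallest
order statistic whose ECDF reaches q; always a sample member) reproduces
the overall median 18.5 and quartiles 9.9 / 24.2 of the 28 PAFs (their
14th, 7th and 21st order statistics), while `midpoint` (mean of the two
central order statistics for an even-sized median) reproduces the
neurological (26.1) and lung (33.6) category medians. Neither convention
reproduces all published numbers alone, so the defaults are
overall=`inverse_ecdf`, category=`midpoint` — fidelity to the published
summaries over internal consistency — and both are selectable. For odd
sample sizes (e.g. the nine cancers, median 8.26) the conventions agree.

## Mortality linkage

Attributable deaths are `deaths × PAF/100`, kept fractional until report
time to avoid accumulation error; the overall attributable percentage is
`100·Σ attributable / Σ deaths`, i.e. the death-weighted mean PAF, which
always lies between the smallest and largest matched PAF. Matching is
exact-string on disease name with an optional user alias map (mortality
sources rarely use twin-table labels verbatim, e.g. "Ischemic heart
disease" vs "Coronary heart disease death"). The packaged mortality table
is synthetic — invented round counts on a Western-European scale, labelled
as such — because real burden-of-disease figures are external data; results
on it demonstrate the arithmetic, not real attributable burdens.

## Synthetic-cohort generator

The generator's primary interface is the pair-outcome multinomial
`(p_both, p_one, p_neither)`; any triple can be injected. As a convenient
parameterisation, the liability-threshold model gives each pair a standard
bivariate-normal latent liability with within-pair correlation r ∈ [0, 1],
and a twin is affected when liability exceeds `Φ⁻¹(1−K)` for lifetime
prevalence K ∈ (0, 1). Then `p_both` is the upper orthant probability and
`p_one = 2(K − p_both)`. The orthant probability has no closed form for
general r; it is evaluated as the 1-D integral
`∫_t^∞ φ(x)·Φ̄((t−rx)/√(1−r²)) dx` by adaptive quadrature (absolute
tolerance 1e−10, well inside the 1e−8 the package promises), with r = 0
(K²) and r = 1 (K) exact. Tests cross-check it against scipy's bivariate
normal CDF and a 10⁷-draw Monte-Carlo oracle.

"True" P, RR and PAF of a generating triple are the count formulas applied
to expected proportions (unexposed risk `p_one/(p_one+2·p_neither)`), with
the same degenerate conventions; r = 0 gives RR = 1 and PAF = 0, r = 1
gives PAF = 100. True PAF is numerically nondecreasing in r at fixed K.

What the generator emulates: the multinomial pair-count structure the
estimator assumes, at realistic prevalences (1–20%) and liability
correlations (0–0.9), with cohort sizes (10⁵ pairs) on the scale of the
Nordic twin registries behind the bundled table. What it does not emulate:
exposure covariates, ascertainment and response bias, zygosity
misclassification, age structure and censoring, or overlap between
registries — so passing recovery tests shows estimator consistency under
the stated sampling model, not robustness to those real-data features.

## Parameter-recovery tolerances

Recovery tests simulate 10⁵-pair cohorts over K ∈ {0.01, 0.05, 0.2} ×
r ∈ {0, 0.3, 0.6, 0.9} with fixed seeds. The sampling noise of the
estimated PAF is quantified by a delta-method standard error propagating
the multinomial covariance through the PAF formula (`paf_standard_error`);
at K = 0.01 this SE reaches ≈1.2 percentage points (concordant pairs are
rare), so tolerance bands are 3 such SEs, or 2% relative where that is
wider. Independence scenarios (r = 0) are checked as RR within 3
delta-method SEs of 1 on the log scale and |PAF| within 3 SEs of 0.

## Statistical uncertainty

The bundled table publishes point estimates only. For user data,
`bootstrap_interval` provides percentile 95% intervals by resampling the
N_T pairs from the multinomial `(N_C, N_D, N_T−N_C−N_D)/N_T` — pairs being
the sampling unit — recomputing the statistic per resample and skipping
resamples where it is undefined; 2000 resamples by default, fully seeded.

## Known limitations

- PAFs bound genetics *plus shared environment*; they are upper bounds on
  neither component separately and assume the published cohorts represent
  their source populations.
- The monotonicity of PAF in N_C (at fixed N_T, N_D) holds only while twins
  with an affected co-twin are the minority; the implementation returns the
  formula's value either way and flags RR < 1.
- One value in the bundled reference statistics is internally inconsistent
  at print precision (the Parkinson concordance digit); the package
  reproduces the value implied by that row's own counts, RR and PAF.
- Exact-string mortality matching is deliberate; fuzzy matching would trade
  silent mislinkage for convenience.
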