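# Methods

This note documents the statistical model, the estimation choices, the
synthetic-data generator, and the numerical conventions used throughout the
package, in the order data flows through the pipeline.

## Exposure model

**Drinker status.** Respondents are classified from two indicators:
no past-year drinking → lifetime abstainer; past-year but not past-month →
former drinker; both → current drinker. Rows with a missing indicator are
excluded with a logged count. The three prevalences are Horvitz-Thompson
weighted shares per sex-age stratum and sum to one by construction.

**Quantification.** The three drinking items (frequency of drinking,
typical drinks per occasion, frequency of heavy episodic drinking) are
mapped to grams of pure alcohol per day as
`occasions/day × drinks/occasion × grams per standard drink`.
Category midpoints follow the standard instrument coding: frequency
never / monthly-or-less / 2-4×month / 2-3×week / 4+×week map to 0, 0.5 and
3 occasions per average month (365.25/12 days), and 2.5 and 5.5 occasions
per week; quantity 1-2 / 3-4 / 5-6 / 7-9 / 10+ map to 1.5, 3.5, 5.5, 8 and
12 drinks. One standard drink defaults to 14 g of ethanol (configurable);
these tables live in `aafengine.constants`.

**Heavy episodic drinking (HED).** HED status (5+ drinks on one occasion
for men, 4+ for women) is read from the dedicated HED-frequency item: any
report of at least monthly episodes marks the respondent as HED. A numeric
drinks-per-occasion value is also compared with the sex threshold, but a
*categorical* quantity item alone never triggers HED — the categories pool
episodic and steady drinking patterns, and using their midpoints as an
occasion threshold misclassifies heavy steady drinkers. The 60 g/day
threshold is never applied to individual respondents; it enters only inside
the AAF integration (below). `p_hed` is the weighted HED share among
current drinkers.

**Calibration.** Self-reported consumption underestimates true intake, so
every current drinker's grams/day is multiplied by one factor per survey
wave:

    f = coverage × benchmark (converted to per-capita g/day) / survey per-capita g/day

with per-capita computed over the full weighted frame (drinkers and
non-drinkers) and litres of pure alcohol converted at density 0.789 g/ml
over a 365.25-day year. `coverage` (default 1.0) expresses what fraction of
the benchmark the adjusted survey should reproduce — the comparative-risk
literature often uses 0.8; it is a configuration knob, never hard-coded.
Calibration is exactly multiplicative, preserving all consumption ratios.
Calibration precedes gamma fitting; the alternative order is not
implemented because fitting first and rescaling the gamma scale parameter
is equivalent for a scale family and would differ only through the cap.

**Gamma smoothing.** Per stratum, a gamma distribution is fitted to the
calibrated grams/day of current drinkers by weighted maximum likelihood.
The untruncated MLE solves the profile equation
`log k − ψ(k) = log(weighted mean) − weighted mean log` by Newton
iteration; because the consumption model is the gamma *truncated and
renormalized* on (0, 150] g/day, the final estimate maximizes the truncated
likelihood (Nelder-Mead on `(log k, log θ)` started at the untruncated
solution, tolerances 1e-8/1e-12). The truncated likelihood matters: fitting
an untruncated gamma to capped data biases the scale downward by roughly
10-15% at realistic parameters. Degenerate inputs (zero variance) fall back
to method of moments with a logged warning; a stratum with fewer than 10
positive observations borrows the nearest same-sex age group's parameters,
also logged.

**Oldest-age carry-forward.** The survey frame stops at age 64, while
mortality extends beyond it. Analysis age groups above the survey ceiling
receive a copy of the oldest surveyed group's distribution per sex and
year, flagged `imputed` in the output for audit.

## AAF computation

For each stratum × partially attributable cause,

    AAF = N / (N + 1),
    N = P_form (RR_form − 1) + ∫₀^cap P_CD(x) (RR_CD(x) − 1) dx,

with `P_CD(x) = p_current ×` truncated gamma density (normalized by the
analytic CDF at the cap). Risk curves are constant (`exp(β₀)`), log-linear
(`exp(β₁x)`) or log-quadratic (`exp(β₁x + β₂x²)`); current-drinker forms
equal 1 at zero dose by construction. RR below 1 (protective ranges of the
ischemic J-curve) is allowed, and negative AAF contributions are retained,
not floored.

**Integration.** Composite trapezoidal rule on 1,501 equally spaced points
on [0, 150] (0.1 g steps, configurable). The point mass at exactly zero
consumption belongs to abstainers and former drinkers, so the integrand is
taken as its limit 0 at x = 0 (for current forms RR(0) = 1, so the limit is
0 even where a shape < 1 density diverges). Constant-RR segments are
integrated analytically — the constant factors out and multiplies the
segment's exact probability mass — which removes quadrature error where
none is needed and makes closed-form cases exact. The trapezoid error of
the remaining smooth integrands behaves like h^(1+k) near the origin: at
the 0.1 g step it is below 1e-6 relative for gamma shapes ≥ 1.2 (the range
fitted consumption distributions occupy) but grows to ~2e-6 as the shape
approaches 1; grid-refinement checks (1,501 vs 15,001 points, < 1e-5) guard
adequacy in the test suite.

**HED decomposition.** For HED-stratified causes the current-drinker
integral splits at 60 g/day: below the threshold the density carries weight
`(1 − p_hed)` on the non-HED curve and `p_hed` on the HED curve; above the
threshold the *full* current-drinker mass is evaluated under the HED curve.
This convention makes the decomposition exactly collapse to the
unstratified integral whenever the two curves coincide (a conservation
property the test suite enforces at 1e-10); weighting the above-threshold
mass by `p_hed` would instead drop `(1 − p_hed)` of the density. Both risk
groups share one consumption density per stratum — the survey fits one
gamma per sex-age group — differing only in mixing weights. A
`excess_risk=False` switch evaluates the integrals with RR instead of
RR − 1 for sensitivity analysis only; the default is excess risk, which the
N/(N+1) transform requires.

Fully attributable causes (e.g. alcohol use disorders, F10) have AAF ≡ 1
with no integration.

## Attribution and rates

ICD-10 codes are normalized (decimal stripped) and matched to the cause
catalog by longest prefix; catalog entries may be single 3- or 4-character
codes, prefixes, or same-letter ranges (`I20-I25`, expanded to 3-character
prefixes). Unmatched codes go to an unmapped bucket that counts toward
total deaths with zero attribution; malformed codes warn and count as
unmapped. Deaths below 15 (the exposure frame's lower bound) are excluded
from attribution and, by default, from proportion denominators
(`include_under_min_in_totals=True` adds them to totals only).

Attributable deaths are `AAF × count` per cell; negative cells from
protective AAFs are retained in sums. Crude rates divide by population;
age-standardized rates are `Σ w_g (deaths_g / pop_g) × 100,000` with the
WHO World Standard (2000-2025) weights collapsed to the four analysis age
groups and renormalized over 15+ (weights ≈ 0.333 / 0.289 / 0.216 / 0.162);
any weight vector summing to one may be substituted.

## Monte Carlo uncertainty

Default 10,000 iterations (pipeline runs in this repository use 2,000,
which changes interval endpoints by less than the Monte Carlo noise they
quantify). Per iteration, jointly:

- status shares from a multinomial with the stratum's effective sample size
  (respondent counts by default; design effects are ignored — the survey's
  cluster design is out of scope), giving binomial marginals for the former
  and current proportions; `p_hed` from a binomial among drinkers;
- gamma parameters by parametric bootstrap: simulate an
  effective-sample-size draw from the fitted gamma, refit by MLE
  (vectorized over iterations via the sufficient-statistics Newton solver),
  bounded retries on failure;
- log-RR coefficients from N(β, Σ) (multivariate where the form has two
  coefficients), drawn once per risk function and shared across strata
  within an iteration so each iteration sees one coherent risk curve.

AAFs are recomputed per draw on the same integration grid. Intervals are
the 2.5/97.5 empirical percentiles with linear interpolation between order
statistics (the convention where draws 1..10,000 give a 2.5th percentile of
250.975). Derived quantities — attributable counts, rates, proportions —
are transformed per iteration from the same draw matrix and only then
summarized, preserving full dependence; interval endpoints are never
summed. Death counts are treated as fixed (no Poisson perturbation of the
registry).

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes; its
defaults are a Chile-like world: past-month drinking prevalence ~52%/40%
declining with age for men/women, ~15-18% former drinkers, HED among
drinkers from 55% (young men) to 18% (older women), calibrated consumption
means of ~39-47 g/day (men) and ~16-22 g/day (women) with gamma shapes
1.2-1.4, per-capita consumption ≈ 6 L of pure alcohol per adult per year,
and cause-specific baseline mortality rising steeply with age (background
non-alcohol mortality dominates, as in real registries). Survey respondents
are allocated to strata proportionally to population, aged 15-64 (so the
60+ analysis group is represented by 60-64-year-olds, exercising the
carry-forward assumption at the data level), with weights = stratum
population / stratum sample size.

Current drinkers' true intake is drawn from the stratum's truncated gamma
by inverse CDF and *discretized onto the item grid by mean-preserving
stochastic rounding* between the two neighboring (frequency, quantity)
pairs — the discretized value is unbiased for the drawn one within the grid
range, so categorization coarsens but does not systematically shift the
fitted distribution. HED status is encoded in the HED-frequency item
(monthly/weekly/daily for HED, never/less-than-monthly otherwise); a
heavy-but-steady non-HED respondent can therefore report a high quantity
category with HED-frequency "never", an inconsistency real surveys also
contain and which the classifier resolves in favor of the dedicated item.

Mortality counts per stratum × cause are Poisson with mean
`population × baseline rate × (N + 1)`, where the baseline rate is the
counterfactual no-alcohol rate and N the stratum's true excess-risk
numerator, so the true AAF `N/(N+1)` is available in closed form; ICD-10
codes are sampled from the cause's catalog prefixes (half with a random
fourth character, exercising prefix matching), and configurable background
mortality uses codes outside the catalog. The benchmark series divides the
scenario's true per-capita consumption by an `undercoverage` fraction, so
calibration with `coverage = undercoverage` recovers truth exactly. Ground
truth (AAFs by adaptive quadrature — a code path independent of the
pipeline's trapezoid — expected deaths, attributable expectations,
standardized rates) is exported per stratum × cause.

What the generator does **not** emulate: the three-stage cluster design's
variance structure (only weights), item nonresponse, reporting heaping,
secular trends within a scenario, and correlation between drinking and
background mortality. Passing tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not robustness
to real-world survey pathologies.

## Verification design

The test suite checks, among others: closed-form constant-RR AAFs to 1e-9
(including negative AAFs); trapezoid-vs-adaptive-quadrature agreement to
1e-6 relative over randomized gamma × log-quadratic fixtures (shapes
1.2-3.5, the smooth regime discussed above); exact collapse of the HED
decomposition under identical curves; recovery of gamma parameters within
15% and of per-capita consumption within 1e-6 from a one-stratum
10,000-respondent survey under 60% benchmark coverage; full-pipeline AAF
recovery within Monte Carlo error on a 2-sex × 4-age × 3-cause scenario,
with replicate mortality attribution centred on the scenario expectation
(200 replicates, 3 SE); and 95%-interval calibration across 200 randomized
scenarios (coverage required in 90-99%), where each scenario's true risk
coefficients are drawn from the same meta-analytic distribution the
simulation propagates so that all three uncertainty sources carry genuine
error. Problem sizes (10,000 respondents, 2,000 iterations, 200
replicates/scenarios, population scales 0.02-0.1) are chosen so the whole
suite runs on one CPU in a few minutes while keeping statistical checks at
3-4 standard errors.

## Known limitations

- Relative-risk coefficients are user configuration; the shipped set is
  illustrative and the central reproducibility gap for substantive reuse.
- Functional forms are limited to constant/log-linear/log-quadratic;
  spline dose-response curves are not supported.
- Single underlying cause of death; no garbage-code redistribution, no
  multiple-cause analysis, no morbidity (YLD/DALY) outcomes.
- Survey design variance (clustering, stratification) is ignored; the
  Monte Carlo treats effective sample sizes as simple random samples.
- Non-survey years inherit the nearest survey wave's exposure (ties toward
  the earlier wave); no interpolation of prevalences is attempted by
  default.
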