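# Methods

## The liability-threshold model

Every analysis in this package rests on one generative assumption: an
individual's ordinal status (non-depressed = 0, minor = 1, major = 2)
is a discretisation of an unobserved liability L ~ N(0, 1) by strictly
increasing cutpoints t₁ < t₂, with status = #{tⱼ < L}. A liability
exactly at a cutpoint goes to the *lower* category — a measure-zero
convention fixed for determinism. Cutpoints are recovered from target
prevalences by normal quantiles: t₁ = Φ⁻¹(1 − P(any depression)),
t₂ = Φ⁻¹(1 − P(major)).

Within a twin pair, liabilities are bivariate normal with correlation
r = a² + c² + d² (MZ) or ½a² + c² + ¼d² (DZ), where a², c², d², e² are
the additive-genetic, common-environment, dominance and
unique-environment proportions of liability variance (non-negative,
summing to one). C and D cannot be separated from twin pairs alone, so
the admissible models are exactly ACE, ADE, AE, CE and E.

Age and sex act as linear shifts of the thresholds on the probit scale:
t'ⱼ = tⱼ + β_age·(age − age_ref) + β_sex·male. The same shift applies
to every threshold (a parallel-threshold assumption), which makes the
threshold-shift and liability-mean-regression formulations numerically
identical; category-specific covariate effects are deliberately out of
scope. age_ref is the cohort mean age, so β_age is centred.

## Synthetic cohorts

`synthetic_cohort.simulate_cohort` draws pair liabilities directly from
the bivariate normal above — one seeded `numpy` generator threaded
through all draws, no global state — and returns exact group sizes per
zygosity/sex group. Two presets encode the cohort structures the
package is designed around:

| preset | pairs (MZ/DZ) | ages | prevalences (minor/major) | a² | β_sex |
|---|---|---|---|---|---|
| `aged` | 643 / 577 | 50–92 | 8.98% / 2.05% (current) | 0.47 | 0.136 |
| `te` | 1005 / 1358 | 23–38 | 7.70% / 37.41% (lifetime) | 0.40 | 0.289 |

The preset a² values are the three-category AE heritabilities the two
cohort analyses are expected to produce; β_sex is the probit-scale gap
implied by each cohort's sex-specific two-category prevalences, and
β_age defaults to 0 because no age-trend magnitude is available —
covariate machinery is exercised by tests with explicit nonzero
coefficients instead. Ages are uniform over the range: only mean, SD
and range are known, uniform keeps the generator dependency-free, and
the choice is swappable.

The DSM-IV classifier maps 9 binary symptom indicators (positions 1–2
being the core symptoms, depressed mood and anhedonia) to major (≥ 5
symptoms including a core one), minor (2–4 including a core one) or
non-depressed. The optional symptom-vector generator draws a count
uniformly from the category-consistent range and forces a core symptom
for affected categories; only the classification *rule* is
scientifically constrained, not the symptom distribution, and the
generator guarantees classifier-consistency by construction.

What the generator does *not* emulate: questionnaire measurement error,
recall effects distinguishing current from lifetime diagnoses, age
trends in prevalence, assortative mating, and sex-specific genetic
effects. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those real-data
features.

## Bivariate-normal kernel

All likelihoods reduce to rectangle probabilities of the standard
bivariate normal. These are computed by Genz's Gauss–Legendre
algorithm (6/12/20 nodes by |ρ|, with the tail-transformed branch for
|ρ| > 0.925), vectorised over bounds, with ±∞ bounds reduced to
univariate tails and ρ = ±1 handled as one-dimensional limits rather
than quadrature. Accuracy is ~10⁻¹⁵, verified in the test suite
against scipy's independent CDF implementation, dense `dblquad`
integration, and the closed-form orthant probability
¼ + arcsin(ρ)/2π. The kernel was written in-house because the fitting
loops need millions of evaluations and microsecond cost; the
independent oracles remain in the tests.

## Polychoric correlation and the multiple-threshold fit test

`fit_polychoric` maximises the multinomial likelihood Σ nᵢⱼ log pᵢⱼ(ρ, t)
jointly over ρ and the cutpoints (one-stage ML; twin tables are small
and the joint likelihood is the cleaner object). Optimisation runs on
transformed scales — Fisher z for ρ, first threshold plus log-spacings
for the cutpoints — so the constraints are implicit; four fixed ρ
starting values make the result deterministic. Thresholds are equated
across co-twins by default (exchangeable same-sex twins; switch off for
opposite-sex tables). The ρ confidence interval is profile-likelihood
based (deviance rise of χ²₁,0.95). A margin with fewer than two
non-empty categories yields an explicit non-estimable result, rendered
"—" by the reporting layer, rather than an exception.

The multiple-threshold goodness-of-fit statistic is
χ² = Σ (Oᵢⱼ − Eᵢⱼ)²/Eᵢⱼ with Eᵢⱼ = n·pᵢⱼ(ρ̂, t̂) and
df = (k² − 1) − (#free thresholds + 1) — standard multinomial
accounting: free cells minus fitted parameters (5 for a 3×3 table with
shared thresholds). The convention is validated behaviourally rather
than against any particular legacy implementation: under the null the
statistic's mean tracks df and the 5%-level rejection rate sits in
[0.04, 0.06] over 2000 simulated tables. No continuity correction is
applied to zero cells; a fitted cell probability below 10⁻¹² with a
positive observed count makes the statistic non-estimable with a
reason. For combined zygosity groupings the reporting layer pools the
tables before fitting (labelled as pooled); an equality-constrained
multi-group fit is a possible alternative reading and is deliberately
not conflated with it.

## Variance-component fitting

`fit_model` maximises the sum of per-pair rectangle log-likelihoods.
Without covariates the data collapse to MZ and DZ contingency tables
(plus marginal counts for singleton twins under individual-level
exclusion), making fits and profile searches fast; with covariates the
likelihood is evaluated per pair, vectorised. Variance proportions are
parametrised through square-root path coefficients normalised to sum
to one (uₐ, u_c free; a² = uₐ²/(1 + Σu²), e² = 1/(1 + Σu²)), which
keeps every estimate in the unit simplex without constraints and lets
components sit exactly at zero. Five fixed variance-proportion starting
points spanning the simplex guard against local optima; ties break by
lowest −2LL, so fits are deterministic. L-BFGS-B convergence tolerances
are 10⁻¹¹ on the objective and 10⁻⁷ on the gradient norm.

Model comparison: likelihood-ratio χ² with df equal to the difference
in free variance parameters, against the *central* χ² distribution.
The boundary-mixture reference (components constrained non-negative)
would halve small p-values; the central convention is the default
because it matches standard twin-modelling reporting practice, and the
LRT p-values recomputed from published −2LL pairs in the acceptance
suite confirm it. AIC = −2LL + 2·(free parameters), counting variance
parameters, thresholds and covariate coefficients; other AIC
conventions differ by data-dependent constants, so only AIC
*differences between models fitted to the same data* are meaningful
here, and ranking behaviour is what the tests assert.

Profile CIs find where the profiled −2LL rises 3.84 above its minimum,
profiling out thresholds, covariates and the remaining free proportion
(a sigmoid weight splits the residual mass when two proportions stay
free); endpoints are clamped to [0, 1], so boundary-truncated intervals
like (0.00–0.83) are expected output, not errors. Opposite-sex DZ
pairs are pooled with same-sex DZ pairs under the same ½/¼
coefficients — no sex-limitation model, by design. For the
"minor-only"/"major-only" classifications that exclude one category,
the default drops the whole pair when either twin is excluded;
`exclusion="individual"` instead retains the remaining twin's marginal
ordinal-probit likelihood, and both modes are exposed because the
choice is a genuine analysis fork.

## Broadened-phenotype power simulation

A biallelic variant with genotype g ~ Binomial(2, maf) shifts liability
by β(g − 2·maf), with the residual variance scaled so total liability
variance stays 1 and thresholds keep their prevalence meaning.
Individuals are rejection-sampled into major / minor / control strata
of fixed sizes (default 3664 / 620 / 7113), and the 1-df
Cochran–Armitage trend test — the score-test core of the logistic
regression an association study would run; sex is not simulated — is
applied with narrow (major-only) and broad (major + minor) case
definitions on the same replicates. β is calibrated to a target
major-vs-control allelic odds ratio by bisection on the *exact*
expected stratum allele frequencies (the large-sample limit of the same
generative model), making the calibration deterministic rather than
Monte-Carlo noisy. Default thresholds correspond to the lifetime
prevalences (7.70% minor, 37.41% major), since case-control cohorts of
this composition are lifetime-classified.

**A structural caveat discovered by this implementation.** Under this
model the broad definition is *not* guaranteed to win. Writing λ for
the minor-case genotype enrichment relative to major cases,
λ = (E[L|minor] − E[L|control]) / (E[L|major] − E[L|control]), the
trend-test non-centrality ratio broad/narrow is
(n_eff,broad/n_eff,narrow) · ((n_major + n_minor·λ)/(n_major + n_minor))²,
where n_eff is the case-control harmonic size. At 3664/620/7113 the
break-even is λ ≈ 0.66, while truncated-normal means give λ ≈ 0.54 at
the lifetime thresholds (and ≈ 0.67 at the older-cohort current-
depression thresholds): the dilution from weakly enriched minor cases
offsets the 17% case-count gain almost exactly, and the simulated
power difference is zero to slightly negative. The acceptance suite
states the increased-power expectation as a test and the simulation
reports whatever the model yields; the test documents, rather than
hides, this tension. A broad definition *does* win under this model
when the minor stratum is relatively larger or its band sits closer to
the major cutpoint.

## Relative risks

RR = P(co-twin affected | proband affected) / P(co-twin affected |
proband non-depressed), on tables first symmetrized for same-sex groups
by the half-sum (C + Cᵀ)/2 — averaging over the choice of proband while
using each pair exactly once, so CI widths are honest; half-counts are
permitted. Opposite-sex tables are never symmetrized (proband sex is
meaningful) and are oriented by the requested proband sex. The 95% CI
is the Katz log-normal interval exp(log RR ± 1.96·√(1/x₁ − 1/n₁ +
1/x₀ − 1/n₀)), isolated behind one function so a bootstrap alternative
can be swapped in; its coverage is verified at 93–97% over simulated
tables. Zero exposed margins, zero reference risk or zero
exposed-outcome counts produce reason-coded non-estimable results.

## Problem sizes and tolerances

Simulation-based checks use sizes at which Monte-Carlo error is small
relative to the tolerance being asserted: n = 10⁵ tables for ±0.02
correlation recovery, 2000 replicates for null calibration of the GOF
test (rejection-rate band [0.04, 0.06]), 100 replicates of 10⁴ pairs
for biometric recovery (mean within 0.02, CI coverage [0.93, 0.97]),
40 paired replicates for the two- vs three-category agreement (mean
difference within 3 MC standard errors), and 2000 replicates for the
power comparison. Kernel accuracy is asserted at 10⁻⁸ against oracles.
Single-draw unit tests use ~3-MC-SD tolerances.

## Known limitations

- No sex-limitation models (quantitative or qualitative), extended
  pedigrees, or multivariate twin models.
- The central-χ² LRT convention is anti-conservative for boundary
  components; the effect is second-order for the comparisons made here
  but matters for marginal p-values.
- The GOF test's χ² approximation degrades when expected cell counts
  fall below ~1; with a 2% major-depression prevalence this limits very
  small per-group tables.
- The power module omits covariates and linkage disequilibrium; it
  addresses the case-definition question only.
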