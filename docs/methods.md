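# Methods

This note records the modelling conventions, defaults, and open design
choices behind `modcare`, in the spirit of a statistical software methods
appendix. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Survey instrument and data model

The demand instrument has five dimensions covered by 19 items
(life assistance 5, medical care 6, spiritual/cultural engagement 3,
rights protection 3, age-friendly modifications 2), each item on a 1–5
Likert scale. A *dimension score* is the unweighted mean of its items.
This aggregation rule is an inference: published dimension medians such as
19/6 ≈ 3.17 and 10/3 ≈ 3.33 are only attainable as unweighted item means.
A dimension's *score rate* is `100 × (cohort mean dimension score) / 5`,
reported to two decimals; the source material uses the term without
defining it, so this is a documented convention chosen to reproduce
plausible magnitudes, not an established fact.

Demographics are eight categorical factors, dummy-coded against fixed
reference categories: age 60–65 (bands 66–70, 71–80, ≥81), junior-high
education or below (vs senior-high or above), with spouse (vs none),
≤1 child (vs ≥2), not living alone, fully independent (vs disabled, i.e.
partially or completely unable to self-care), no chronic disease, and
monthly income 0–1,500 yuan (bands 1,501–3,000 / 3,001–4,999 / >5,000).

## 2. Synthetic cohort generator

No survey microdata are deposited, so cohorts are simulated.

**Demographics.** Factors are drawn independently from marginal
prevalences; the packaged defaults are the study sample's marginals
(age bands 32.63/22.36/33.23/11.78%, 24.47% higher education, 28.40%
without spouse, 52.57% with ≥2 children, 17.22% living alone, 19.64%
disabled, 71.00% chronic disease, income bands 8.46/41.69/34.14/15.71%).
Only marginals are published, so independence is the default; an optional
conditional-probability override (`p_living_alone_by_spouse`) lets users
couple solitary living to spouse status when a joint structure is wanted.

**Latent scores.** Each dimension has a latent score
`intercept + Σ effects(possessed categories) + N(0, noise_sd)`.
The packaged ground truth uses the published unstandardized regression
coefficients (all of them, significant or not) as true effects and the
published constants as intercepts, so the generator is exactly the data
generating process the downstream regression assumes — which is what makes
parameter-recovery testing meaningful. Items within a dimension share the
dimension latent and add independent per-item `N(0, noise_sd)` noise, so
dimension means are less noisy than single items, as in any multi-item
instrument. Item responses are the per-item latent rounded
**half-away-from-zero** and clamped to [1, 5]. The rounding convention is
stated explicitly because it changes recovery behaviour at band edges.

`noise_sd` defaults to 0.6. No in-source calibration target exists
(inter-item correlations and score variances are unpublished); 0.6 was
chosen once so that simulated dimension medians and interquartile ranges
have a spread comparable to the published descriptive table, and is
configurable.

**Reproducibility.** One integer master seed; respondent *i* draws its
profile from substream `(seed, i, 0)` and its items from `(seed, i, 1)`.
Cohorts are therefore byte-stable and *prefix-stable*: extending a cohort
never changes earlier records.

**What the generator does not emulate.** Real Likert data show
acquiescence and central-tendency response styles, item-specific factor
loadings, demographic joint structure, and missingness — none are
modelled. Passing recovery tests therefore demonstrates internal
consistency of the estimation pipeline under its own assumptions, not
robustness on real survey data.

## 3. Statistical analysis

**Univariate screening.** Two-level factors: Mann–Whitney U with
mid-ranks, reported as the tie-corrected asymptotic Z with two-sided
normal p, *without* continuity correction — this keeps the classical
identity H = Z² exact for two tie-free groups and matches the convention
of reporting Z itself. An exact-enumeration p (`exact=True`) exists for
pooled n ≤ 14; the production path stays asymptotic at all n, matching the
source analysis. K ≥ 3 level factors: tie-corrected Kruskal–Wallis H with
a χ²(k−1) reference. The source tables label K-group statistics "F"; they
are H statistics and are labelled as such here, with a note emitted in CLI
output metadata. Factors with any dimension p < 0.05 (strict) enter the
model; no multiple-testing correction is applied, faithfully reproducing
the per-test α = 0.05 plan.

**Regression.** OLS with all screened factors entered simultaneously
("Enter" method, no stepwise selection), dummy-coded against the reference
categories above; reference rows are emitted with B = 0 as in conventional
tables. Standardized betas are `B·sd(x)/sd(y)`. Tolerance/VIF come from
auxiliary regressions (`VIF = 1/(1−R²_aux)`); perfect collinearity is
reported as infinite VIF and, at fit time, raised as an error naming the
collinear columns. Durbin–Watson uses residuals in input row order —
the row ordering is otherwise unspecified, so it is part of the contract.
Diagnostics are *reported, not gated*: no numeric pass/fail criterion is
imposed on them (none is defined in the source plan).

**Percentiles.** Median/P25/P75 use the positional `(n+1)p` rule with
linear interpolation, positions clamped to [1, n] (numpy `"weibull"`,
SPSS HAVERAGE) — the convention of the statistics environment the source
analysis used. The rule name is stored in `ThresholdSet.provenance`.
Note this rule is only asymptotically duplication-invariant: duplicating a
sample can shift an interpolated percentile by up to one inter-order-
statistic gap, which is how the property is tested.

## 4. Bundle engine

**Activation.** α = 1 iff dimension score ≥ P75 threshold; equality
activates (fixed by the published boundary case where a score of 4.0
against a threshold of 4.0 activates).

**Weighting.** β sums the *unstandardized* B column over significant
(p < 0.05) predictors the person possesses. The surrounding text says
"standardized coefficients (B values)", which is self-contradictory; the
published worked sums (0.287 + 0.206 + 0.381 + 0.403 = 1.277 etc.) are
only consistent with the unstandardized column, so B it is.

**Worked-example discrepancy.** The stated rule would add the chronic
disease coefficient (B = 0.170, p = 0.026) to the example's life-assistance
weight, but the published sum omits it. The engine's default mode applies
the stated rule to full profiles (yielding 1.447 for that module); a
strict-example mode accepts explicit per-module predictor sets so the
published 1.277/1.418/1.021 are reproducible bit-for-bit. Unstated
attributes default to reference categories and contribute 0.

**Representation.** A bundle is a weighted set of module identifiers
(module → α·β) plus the contributing (predictor, B) pairs — not a scalar:
the Σₖ over modules is symbolic, and summing weights across unlike service
modules has no interpretation.

**Tiering.** Tier-1 priority is the union (OR) of advanced age (≥71),
living alone, and disabled. The source sentence lists the three groups
jointly without stating a combination rule; the union reading treats them
as alternative priority populations, and the triggering attributes are
returned so a stricter policy can be layered on.

## 5. DSMI monitoring

`DSMI = (actual coverage / expected coverage) × satisfaction`, all three
operands as fractions in [0, 1] with satisfaction = mean 5-point rating / 5.
None of the operands is operationally defined at the source, so these are
package conventions. DSMI may exceed 1 (over-delivery) and is not clamped;
the trigger concerns only the low side: DSMI ≤ 0.8 (boundary inclusive)
triggers recombination. The monitoring loop processes a delivery stream in
period order, capped at `max_iter` periods; each triggered period invokes a
rebundle hook (by default re-running the bundle engine on refreshed scores
and thresholds), and a trigger still active at the cap is flagged
unresolved. Alternative escalation policies are out of scope.

## 6. Numerical conventions and degenerate inputs

- Reported percentages round half-away-from-zero to two decimals
  (implemented via decimal arithmetic to avoid binary-float artefacts).
- The sample-size rule `ceil(n_vars · multiplier · (1 + attrition))`
  rounds its product to 9 decimals before the ceiling so that exact
  products (e.g. 19·5·1.2 = 114) are not bumped by float error.
- All pooled values identical ⇒ Z = 0, H = 0, p = 1 (rather than 0/0).
- Empty cohorts, empty groups, mismatched module/score pairs, unknown
  predictor categories, probability vectors off the simplex, and
  `expected_coverage = 0` all raise typed errors (`DomainError` /
  `ConfigurationError`).
- In the packaged coefficient table, p-values printed as "0.000" are
  stored as 0.0 (below printed precision), and the printed
  tolerance/VIF columns carry 3-decimal rounding, so `tolerance·vif = 1`
  holds only to ~1e-3 there; freshly computed tables satisfy it to 1e-9.

## 7. Problem sizes used in the checks

Parameter recovery fits a 20,000-respondent cohort (coefficients recovered
within ±0.05 on the latent scale); type-I error calibration uses 10,000
null replicates of 200-respondent cohorts, a scale at which the asymptotic
rank tests are expected to hold their nominal level on discrete Likert
data; marginal-convergence checks use n = 10,000 with 3-sigma binomial
bands. These sizes are the package's own choices for stable Monte-Carlo
verification.

## 8. Known limitations

- Published subgroup tables and coefficient values cannot be numerically
  reproduced without the raw survey data; the pipeline is validated
  structurally (recovery, calibration, invariants) instead.
- The generator's independence and Gaussian-latent assumptions are
  simplifications (§2 above).
- DSMI operand definitions are conventions; deployments measuring coverage
  differently should recalibrate the 0.8 trigger.
- The CLI monitoring command re-flags bundles but cannot re-score people
  without fresh assessment data; programmatic use of `run_monitor_cycle`
  accepts an arbitrary rebundle hook.
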