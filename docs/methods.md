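# Methods

This note documents the statistical models the package implements, the
synthetic data they are exercised on, the numerical choices, and the
places where a genuinely open design decision was made.

## 1. Survey arm

### 1.1 Estimand and model series

The survey arm estimates the association between a binary drug exposure
and a binary self-reported memory outcome in complex-survey microdata.
Logistic regression gives odds ratios under three nested adjustment
tiers:

| tier | covariates added |
| --- | --- |
| model 1 | none (crude) |
| model 2 | age (linear), gender, race (5 levels), education (3 levels) |
| model 3 | + moderate activity, diabetes, hypertension, caffeine, alcohol, sugar |

Categorical covariates enter as full dummy blocks with the first level as
reference (gender: male; race: Mexican American; education: below high
school; smoking, when used: never). BMI and smoking are carried for
subgroup definitions but are not model-3 covariates.

### 1.2 Estimation and variance

Point estimates maximise the weighted log-likelihood
`Σᵢ wᵢ [yᵢ ηᵢ − log(1+e^ηᵢ)]` by iteratively reweighted least squares.
Convergence is declared when the weighted deviance changes by less than
1e-8, with a budget of 50 iterations; any coefficient exceeding 15 on the
logit scale aborts the fit with a separation error (at that magnitude the
fitted probabilities are numerically 0/1), and a single-class outcome is
rejected up front as degenerate.

Variances are design-based by Taylor linearization. With per-record score
contributions `uᵢ = wᵢ(yᵢ − pᵢ)xᵢ`, summed to PSU totals `z_{hk}` within
stratum *h*:

    G = Σ_h n_h/(n_h−1) Σ_k (z_{hk} − z̄_h)(z_{hk} − z̄_h)ᵀ
    V = A⁻¹ G A⁻¹,   A = Σᵢ wᵢ pᵢ(1−pᵢ) xᵢxᵢᵀ

Confidence intervals and two-sided Wald p-values use a t reference with
design degrees of freedom `df = #PSUs − #strata`. A stratum with a single
PSU ("lonely PSU") is treated as a certainty unit contributing zero
between-PSU variance, with a warning; an `error` policy is selectable.
All estimates, SEs and p-values are invariant to rescaling the weights by
a constant.

Subgroup analyses refit the series within each level of a stratifier
(gender, age bin, BMI bin, smoking, hypertension, activity, diabetes),
dropping the stratifier from its own tier. Age bins are 20–39, 40–60, >60
on integer age (39 and 60 close their lower bins); BMI bins are the
standard <25, 25–30 (inclusive), >30. Levels with fewer than 50 records,
a single outcome class, or a separated fit are skipped with a warning.
Interaction tests add exposure×modifier product terms to model 3 and test
the block with `F(q, df − q + 1)`. No multiplicity adjustment is applied
across subgroups or interactions; outputs note this.

Weighted descriptives report weighted means (weighted SDs) for continuous
variables and unweighted counts with weighted percentages for categorical
ones. Group comparisons are design-adjusted Wald tests built from the
same linearization machinery: a t test on the two-group mean difference
for continuous variables, and for an L-level categorical variable a Wald
statistic on the (L−1)-vector of weighted proportion differences with a
Thomas–Rao-style F reference — a Rao–Scott-type correction implemented as
a Wald test rather than an eigenvalue-corrected Pearson statistic.

### 1.3 Sensitivity analyses

The E-value converts the adjusted OR to the risk-ratio scale — identity
under the rare-outcome approximation (the default: outcome prevalence in
the emulated population is ≈4%), or square-root when the outcome is
declared common — reciprocates protective estimates onto the ≥1 scale,
and applies `E = RR + √(RR(RR−1))`. The CI E-value uses the limit nearer
the null and is 1 when the interval crosses 1.

AUC uses mid-rank placements (half credit for ties), which equals the
exact proportion of concordant case/non-case pairs; the CI is the DeLong
placement-value variance with a normal reference, clipped to [0, 1]. The
default is in-sample and unweighted; a weighted variant uses
weight-averaged placements with effective sample sizes. Note: for an OR
of roughly 0.5 between standard conversions, published E-values can
differ several-fold depending on the chosen conversion and on whether the
point estimate or a CI limit is converted; the package therefore exposes
both conversions explicitly rather than a single number.

## 2. Report arm

Each adverse-event term *e* yields a fourfold table against the
target-drug flag (a: drug ∧ e, b: drug ∧ ¬e, c: other ∧ e, d: other ∧
¬e). Two disproportionality measures are computed:

**ROR** `= ad/bc` with 95% CI `exp(ln ROR ± 1.96√(1/a+1/b+1/c+1/d))`.
Tables with a zero cell raise an error by default; an optional Haldane
correction (+0.5 to all four cells) is applied on request and flagged in
the output. The threshold `a ≥ 3` makes zero-`a` tables non-signals
either way.

**BCPNN information component** under the standard shrinkage priors
α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1 and the data-dependent joint prior total
γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)). The posterior is three independent
Beta laws for p₁₁, p₁·, p·₁, and IC = log₂ p₁₁/(p₁· p·₁). Two evaluation
methods are provided:

- `approx` (default): the conventional closed forms — E(IC) as the log of
  the ratio of posterior means, and the matching three-term variance.
  These are the screening statistics pharmacovigilance practice uses, and
  they drive the signal rule.
- `exact`: the true posterior mean and variance of IC via digamma and
  trigamma functions of the same Beta parameters.

The two agree in the large-count limit; for small drug–event counts the
closed form overstates E(IC) by about `1/(2(a+γ₁₁) ln 2)` bits (≈0.3 bits
at a = 1). The test suite verifies the exact moments against Monte-Carlo
sampling of the posterior at any count, and the approximate ones at
moderate counts where the error is within sampling tolerance.
`IC025 = E(IC) − 2·SD(IC)` is the conventional two-standard-deviation
lower bound, not an exact posterior quantile.

The dual signal rule requires both `a ≥ 3 ∧ ROR CI lower bound > 1`
(strict inequality) and `IC025 > 0`. Signals under the dual rule are by
construction a subset of either rule alone. Terms are ranked by IC025
descending; a composition table of drug-report counts and percentages per
term is emitted alongside. Thresholds are fixed; no multiplicity
adjustment is applied across terms, and synthetic runs report the false
discovery count against known truth instead.

## 3. Synthetic data

### 3.1 Survey cohort

The generator emulates an adult health-survey population: age ~
N(42, 15²) truncated to [20, 85] and floored to whole years; gender 58%
male; the 5-level race and 3-level education distributions at (12, 7, 61,
12, 8)% and (27, 24, 49)%; BMI ~ N(27.8, 4.6²); sugar, caffeine and
alcohol as gamma variables matching means (SDs) of 123 (84), 173 (222)
and 14 (35); smoking 43%; moderate activity 50%; hypertension and
diabetes age-linked with ≈16% and ≈4% marginal prevalence. Weights are
log-normal with SD 0.5 on the log scale, scaled to a population total of
85 million; strata (default 15) and PSUs (2 per stratum) are assigned
uniformly.

Exposure and outcome are Bernoulli draws from logistic models sharing the
confounder score `z_age + hypertension + diabetes` with coefficient
`confounding_strength` (default 0.8); the outcome model adds
`log(true_conditional_or)` (default log 0.47) on the exposure indicator.
Each model carries its *own* independent mean-zero Gaussian PSU random
effect (SD 0.25). Independence between the two effects matters: a shared
PSU effect would act as an unadjusted cluster-level confounder and bias
the adjusted estimate, whereas independent effects induce intra-cluster
correlation (so design-based SEs genuinely exceed iid SEs) without moving
the estimand. Intercepts are calibrated by root-finding so the expected
exposure and outcome prevalences hit their targets (11% and 4.3%) on the
drawn covariates. With these defaults the crude OR sits around 1.3–1.5
while the conditional OR is 0.47 — the Simpson-type reversal the
adjustment series is designed to exhibit. At the default n = 20,000 the
crude log OR is positive with wide margin; at a few thousand records
sampling plus cluster noise can occasionally push it to zero, which is
why small-sample checks test the adjusted-below-crude ordering rather
than the strict sign.

The only non-zero structural coefficients are on age, hypertension and
diabetes, so the fully adjusted tier is correctly specified and
consistent for the planted conditional OR; the remaining covariates are
distributional dressing with null effects.

### 3.2 Spontaneous reports

Each of `n_reports` reports is independently a target-drug report with
probability 0.10 and carries exactly one event term. The background
distribution over the 50-term vocabulary is Zipf(1): public reporting
databases expose drug-side counts but no canonical background
composition, so a heavy-tailed rank distribution was chosen once as
typical of spontaneous-reporting data. A
planted signal (e, λ) multiplies term e's probability among drug reports
by λ before renormalisation; the implied population ROR
`[q/(1−q)]/[p/(1−p)]` is recorded in the ground truth and exposed as
`analytic_ror`. The "study" preset plants λ = 5.2 on "amnesia" and
λ = 3.5 on "delusion", giving analytic RORs ≈ 5.1 and ≈ 3.4.

One event term per report, one drug flag, no duplicates, no time axis —
matching the fourfold-table analysis; everything beyond it is out of
scope.

### 3.3 What passing tests do and do not show

The generators realise exactly the model class the estimators assume
(logistic outcome, one record per participant, non-informative weights,
clean categorical levels). Passing recovery and coverage tests therefore
validates the estimation machinery, not robustness to real-data
pathologies: informative weights, item nonresponse, misclassified
self-reports, duplicate or stacked adverse-event reports, MedDRA coding
drift. Results on real extracts depend on those features and on the
actual external databases, which the package deliberately does not fetch.

## 4. Determinism and sizes

Every dataset derives from a single `numpy.random.default_rng(seed)`
stream; identical parameters give byte-identical CSV output, and the
pipeline manifest records a config hash. Default problem sizes were
chosen so the whole test suite runs in well under a minute of simulation
per property: cohort generation at 5,000–50,000 records, report streams
at 200,000 reports, 500-replicate coverage simulation at n = 5,000,
20-replicate operating-characteristic runs. The acceptance script uses
the same sizes.

## 5. Known limitations

- Taylor linearization only; no BRR/jackknife replicate weights.
- No multi-cycle weight rescaling (weights are taken as given).
- The exclusion cascade's rule order is fixed; per-rule counts depend on
  that order when a record violates several rules.
- The E-value's square-root conversion is a coarse approximation for
  common outcomes; no full bias analysis is attempted.
- AUC is in-sample; no cross-validation or calibration assessment.
- ROR/BCPNN are screening statistics: with fixed thresholds and no
  multiplicity control, borderline background terms occasionally clear
  both rules, and a flagged term is a statistical association, not a
  causal claim.
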