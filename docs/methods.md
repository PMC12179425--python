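# Methods

`twinace` implements the statistical machinery of a classical twin study of
two correlated quantitative traits: simulation of twin-pair data, covariate
screening and residualization with GEE, full-information maximum-likelihood
(FIML) twin models, decomposition of trait covariance into genetic and
environmental sources, and simulation-based power analysis. This note
documents the models, the numerical choices, and the limits of what the
test suite demonstrates.

## The biometric model

For monozygotic (MZ) pairs both twins share all additive genetic variance;
dizygotic (DZ) pairs share half of it on average. Under the ACE model a
trait decomposes into additive genetic (A), shared environmental (C) and
unique environmental (E) variance; E includes measurement error. For two
traits the *correlated factors* parameterization gives each trait its own
A/C/E factors and lets like-type factors correlate across traits with
coefficients rA, rC, rE.

The implied covariance of the stacked pair vector (twin 1's traits, then
twin 2's) has within-person block `Σ_A + Σ_C + Σ_E` and cross-twin block
`Σ_A + Σ_C` (MZ) or `½Σ_A + Σ_C` (DZ), where
`Σ_X[i,j] = r_X √(x²_i x²_j)` and `Σ_X[i,i] = x²_i`. This one function
(`build_pair_covariance`) is shared by the simulator and the likelihood,
so simulated data have exactly the structure the models assume — a
deliberate choice: recovery tests then isolate estimator error from model
misspecification.

On the standardized scale (A + C + E = 1 per trait) the model implies

    rMZ = A + C                         rDZ = A/2 + C
    ctct_MZ = rA·√(A₁A₂) + rC·√(C₁C₂)   ctct_DZ = ½rA·√(A₁A₂) + rC·√(C₁C₂)
    r_ph = rA·√(A₁A₂) + rC·√(C₁C₂) + rE·√(E₁E₂)

and the three terms of `r_ph` are the bivariate contributions biv_A, biv_C,
biv_E. Their proportions of `r_ph` sum to one exactly but individual terms
can be negative or exceed one when contributions have opposite signs; the
package reports them as-is.

## Likelihood and fitting

Each pair contributes the multivariate-normal log-density of exactly its
observed values (rows/columns of the implied mean and covariance deleted
for missing entries), so incomplete pairs need no imputation. Pairs are
grouped by zygosity and missingness pattern and each group's sub-covariance
is factored once per likelihood evaluation.

Parameterization: component standard deviations are unconstrained (the
variance is the square), so `a² = 0` is reachable without an active bound;
correlations pass through `tanh`; saturated covariances use free Cholesky
factors (bivariate) or per-cell log-SDs plus a per-zygosity correlation
(univariate, where the assumption submodels need parameter sharing).
Boundary estimates are reported as-is and flagged in `FitResult.notes`; no
truncation-aware mixture p-values are applied to variance-component tests
(a known, documented limitation — the nominal chi-square reference is
conservative at the boundary, and the power module offers an optional
50:50 mixture reference).

Optimization is L-BFGS-B with central-difference gradients, tolerance
~1e-8 on −2LL, started from moment-based values: per-zygosity sample
moments for saturated models, Falconer estimates (`A ≈ 2(rMZ − rDZ)`,
`C ≈ 2rDZ − rMZ`) plus cross-correlation-based starts for rA/rC/rE for ACE
models. Seeded random restarts (default budget 10) trigger only when a fit
fails; with complete data the saturated starting values are already the
MLE. Non-PD implied covariances return +∞ to the optimizer.

Bookkeeping: `df = (non-missing data points) − k`. AIC = −2LL + 2k.
BIC = −2LL + k·log(n_pairs): pairs, not individuals, are the independent
sampling units, so they set the BIC sample size. Model selection uses BIC
alone (the conservative rule), with the LRT reported for transparency.

The four assumption submodels constrain the univariate saturated model
cumulatively — means equal across twin order, then across zygosity, then
variances likewise — and each is compared to the fully saturated model by
LRT (Δdf = 2, 3, 5, 6). Significant tests warn rather than abort.

Profile (likelihood-based) CIs locate the points where the profile −2LL
rises 3.841 (χ²₁, 95%) above the minimum: an outward geometric march
brackets each bound, bisection refines it, and each inner profile point is
an SLSQP equality-constrained refit warm-started from the previous
solution. Works for natural parameters and derived ones (standardized A/C/E
proportions, correlations). Bounds that run into the parameter domain
(e.g. rA at −1 — which happens routinely for the genetic correlation at
the study's sample size) return the domain edge flagged `*_at_bound`.

## GEE

Covariate screening, residualization and polygenic-score association use
identity-link Gaussian GEE on individual-level data clustered by pair, with
the Liang–Zeger sandwich `B⁻¹MB⁻¹`. The exchangeable working correlation
(the natural choice for twins; independence available by flag) is
re-estimated from Pearson residuals by the moment estimator each iteration.
Response and predictors are z-scored so slopes are standardized; binary sex
is coded 0/1 then z-scored; income and education ordinal ranks are treated
numerically. Wald tests use the normal reference with ±1.96 CIs and no
small-sample df correction (large-sample GEE convention; at ~300 clusters
the empirical size stays near nominal — verified in the test suite).
Screening tests all candidates jointly by default (per-covariate marginal
models by flag) and retains a covariate when p ≤ α on either trait.
Residualization deliberately uses the independence working correlation:
pooled least squares makes residuals exactly mean-zero and orthogonal to
every regressor, and coefficient consistency does not depend on the working
correlation. Polygenic-score associations are reported uncorrected for
multiple comparisons by design.

## The simulator

`simulate_dataset` draws pair vectors from the exact model covariance
(multivariate normal — the traits it emulates are residualized raw scores
with near-zero skewness, and MVN is what the likelihood assumes), adds
covariate effects linearly on the trait mean (covariates are additive by
construction because the analysis residualizes them before twin modelling),
and applies per-twin missingness (default rate 0.01, matching a handful of
incomplete pairs in ~300; a twin is missing wholesale, though per-cell
granularity falls out of the same mechanism). `infant_cohort_spec()` bundles
the study-shaped defaults: 164 MZ + 131 DZ pairs, motor mean 10.27
(SD 1.05) and social-communication mean 34.22 (SD 1.65), standardized
components (0.21, 0.67, 0.12) and (0.12, 0.78, 0.10) with rA = −0.39,
rC = 0.45, rE = 0.32, and pair-level demographic covariates (age, term age,
sex, parental age/education, 11-level income) with standardized effects of
the screened magnitudes (age 0.28/0.15, term age 0.17/0.11, income
−0.19/−0.11, ...). Polygenic-score columns are standard normal with the
design's genetic sharing (MZ identical, DZ correlated 0.5) plus ten
independent standard-normal ancestry PCs; score effects default to zero.

What the simulator does *not* emulate: rater/informant bias (a single
caregiver rating both twins), item-level questionnaire structure, floor and
ceiling effects of short scales, non-normal tails, or ancestry structure in
the PCs. Passing recovery tests therefore show that the estimators are
correct under the model's own assumptions, not that the model is correct
for any particular instrument.

## Power

`posthoc_power` simulates studies at the generating values and design
size, fits the full bivariate model and the nested model with the target
parameter fixed at zero, and counts LRT rejections (default 500
replicates, α = 0.05, per-replicate seeds derived from one seed).
Detection is LRT-based rather than CI-excludes-zero. Fixing e² = 0 makes
the implied MZ covariance singular, so "power for E" is trivially 1 and E
components are excluded from the default target list.

## Problem sizes and tolerances in the test suite

Closed-form sanity checks use 50,000–100,000 pairs (±0.02 on empirical
moments). Parameter recovery runs 200 replicates at the 164 + 131 design
(mean absolute bias ≤ 0.03 on standardized components). GEE size is checked
over 2,000 clustered null replicates ([0.03, 0.07] at α = 0.05). Profile-CI
coverage is checked over 200 univariate replicates at the study design
([0.90, 0.99]); the univariate model exercises the identical profile
machinery as the bivariate one at a fraction of the refit cost. Derived
tolerances (1e-10 for the density oracle, 1e-6 for scale invariance,
1e-12 for algebraic identities) reflect the numerical precision of the
fitting machinery, not sampling error.

## Known limitations

- No ADE/AE/CE model family search, sex-limitation, moderation (G×E) or
  Cholesky/common-pathway alternatives: the correlated-factors ACE model is
  the scope.
- Boundary-aware inference (mixture references, one-sided CIs for variance
  components) is limited to the optional power-analysis flag.
- The exchangeable-α moment estimator can leave the working correlation
  mildly biased in tiny samples; the sandwich keeps the SEs valid
  regardless.
- BIC's sample-size convention (pairs) is one of several defensible
  choices; comparisons between models fitted to the same data are
  unaffected by the convention, but absolute BIC values are not comparable
  across conventions.
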