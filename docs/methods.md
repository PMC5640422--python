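# Methods

This note documents the statistical models the package implements, the
synthetic data-generating process used to exercise them, and the numerical
and design choices made where the methodology left the details open.

## 1. Measurement model for the two capital scales

Binary and ordered-categorical childhood items are modelled with the
underlying-normal (probit threshold, "normal ogive") factor model. Item
*i* has a latent response

    y*_i = λ_i' η + e_i,   e_i ~ N(0, ψ_i),   ψ_i = 1 − λ_i' Φ λ_i,

with unit marginal variance, observed as category *c* when
τ_{i,c−1} < y*_i ≤ τ_{i,c}. η is the vector of factor values with
correlation matrix Φ. This model is what a weighted-least-squares pipeline
for categorical data presumes, and it makes the generator and the
estimators exactly consistent with each other.

**Estimation** is the standard two-step route:

1. *Thresholds* from univariate margins: τ_c = Φ⁻¹(cumulative proportion
   at or below category c).
2. *Polychoric correlations* pairwise, maximizing the contingency-table
   likelihood in ρ with thresholds fixed (bounded scalar optimization on
   [−0.999, 0.999]; a perfectly concordant table hits the clamp). Pairs are
   assembled pairwise-complete; an indefinite matrix is repaired to the
   nearest positive-semidefinite correlation matrix (eigenvalue clipping,
   re-scaled diagonal) with the Frobenius repair magnitude logged, and a
   degenerate pair (constant on its pairwise subset) is left at 0 and
   flagged rather than aborting the matrix.
3. *Factor extraction* by least squares on the polychoric matrix. When the
   matrix is pairwise-complete with very unequal pairwise ns — the normal
   situation here, since experimental-module items are observed for 2–22%
   of respondents while core items reach 60–90% — the extraction and the
   fit statistic weight each pair's squared residual by its pairwise count:

       χ² = Σ_{i<j} (n_ij − 1) (r_ij − r̂_ij)².

   With equal pairwise ns this reduces to the familiar
   (N − 1) × (unweighted discrepancy), which is what the package computes
   when given a plain correlation matrix. The weighting matters: in an
   unweighted fit the handful of module pairs (n ≈ 200) carry as much
   influence as core pairs (n ≈ 6,000), and we found they routinely drag
   the solution into Heywood territory and large residuals on the
   well-measured pairs. The effective N reported with a pairwise matrix is
   the *mean* pairwise count, because the weighted χ² grows as
   (mean pairwise n) × (weighted discrepancy); RMSEA and CFI then use
   their usual formulas,

       RMSEA = sqrt(max(χ² − df, 0) / (df (N − 1))),
       CFI = 1 − max(χ² − df, 0) / max(χ²₀ − df₀, χ² − df, 0),

   with the independence model as the null and df = p(p−1)/2 − p·m (the
   rotational indeterminacy of m(m−1)/2 is spent on the oblique factor
   correlations). A saturated model (df = 0) has undefined RMSEA (reported
   as NaN and flagged).
4. *Geomin rotation*, oblique, ε = 0.01 (the conventional default; the
   source method names the rotation but not ε), by gradient projection
   with 10 random starts (the geomin surface has local minima). Factors
   are reflected so their dominant loadings are positive.

**Structure search** fits 1–3 factors, accepts the smallest count meeting
RMSEA < 0.07 and CFI ≥ 0.95 among candidates with eigenvalue support
(Kaiser count, first factor always supported), drops items whose largest
absolute rotated loading is ≤ 0.3, and refits on the retained set (capping
the factor count at what the retained item count admits). If nothing meets
the rules the best-fitting solution is returned with an explicit failure
flag — never silently.

**Scoring** is maximum a posteriori under the fitted model: for each
respondent, η̂ maximizes the sum of observed-item log-probabilities plus
the log N(0, Φ) prior density. The posterior is log-concave (ordinal
probit likelihoods are log-concave in λ'η), so L-BFGS from the prior mean
finds the global optimum; identical response patterns are scored once and
broadcast. A respondent with no observed scale item receives no score —
this is the full-information property that gives the validated measures
their sample-size advantage. Note the residual scale √ψ_i appears in the
likelihood; a formulation without it would be inconsistent with the data
model whenever communalities differ across items.

**Scales.** Factor scores are summed and z-scored (population convention,
divisor n, used uniformly throughout the package). The
financial-instability factor is reflected (weight −1) before the sum so
the cFC scale points toward more capital, while the factor itself keeps
its higher-=-more-unstable orientation in the component-level regressions.
Raw sums are z-scored without per-factor standardization first (the
alternative is not distinguishable from the source description; this is
the simpler reading).

The "never lived with mother/father" response level of the parental
employment items is recoded to a cause-specific missing sentinel before
the financial-capital model sees it, and the information is routed to the
social-capital scale through the lived-with items. One consequence worth
knowing: the employment items are therefore observed only in the
subpopulation that lived with that parent, a mild real-world violation of
the one-population factor model that shows up as small residuals rather
than as bias in the retained structure.

## 2. Parental education imputation and the human capital index

Education arrives continuous (years 0–17), dichotomized at 8 years, or
missing. Five EM runs under multivariate normality with ignorable
missingness produce conditional-mean single imputations:

* one joint *any-missing* group (both parents' years in the model, so the
  mother–father correlation is exploited), clamped to [0, 17];
* *mother < 8*, *father < 8* (clamped to [0, 8]) and *mother ≥ 8*,
  *father ≥ 8* (clamped to [8, 17]) for the dichotomized sub-cohort.

Each subgroup's EM estimation sample is augmented with the
continuously-reported rows satisfying the subgroup's defining constraint
(e.g. observed years < 8 for the below-8 group); without this the
education–predictor covariance would be unidentified inside a subgroup
whose education is entirely dichotomized. Predictors are demographics
(age, gender, race, southern/foreign birthplace, childhood health) plus
the social items; categorical predictors enter as indicator columns; the
below-8 mother group uses the documented reduced predictor list. A
subgroup too small for its design prunes social predictors last-first,
logged. Observed continuous values are never altered; a clamp audit
(per-subgroup imputed and clamped counts) is written as CSV. A stochastic
variant (conditional draw) exists behind a flag for sensitivity analysis;
the production rule is the deterministic conditional mean. EM convergence
is |Δ log-likelihood| < 1e-6 or 500 iterations, with the monotone
log-likelihood trace retained.

cHC = z(z(mother) + z(father)) is defined for 100% of rows
post-imputation.

## 3. Indices, outcomes, covariates

The validated cSES index is the mean of the available z-scored capitals,
re-standardized; a row missing all three gets no value. The comparison
codings follow their published rules exactly (see the module docstring in
`indices.py`): Luo (standardize-then-average, unknown → low SES, "it
varied" → missing-and-average-the-rest), Glymour (known-low points,
reverse-coded to 0 = lowest), Hargrove (five indicators at the 12-year
education cuts under a complete-case eligibility flag; the
dichotomized-at-8 representation cannot answer a 12-year cut, so those
rows are ineligible — matching the original exclusion of that
sub-cohort). "White collar" is occupation categories 6–4
(executives/managers, professional specialty, sales/administration) and
"manual" 1–2 on the package's 1–6 coding; the cut is a named constant.
Whether the 3-level self-rated item should be standardized as ordinal
numeric before the Luo average is not documented anywhere we could find;
ordinal-numeric is implemented.

The depressive-symptom score sums six negative items and two reverse-coded
positive items (range 0–8); a missing item makes the score missing by
default (prorating to the 8-item scale is available but off).

Comparison regressions are OLS with age (linear, quadratic), gender,
race/ethnicity and birthplace indicators; continuous predictors z-scored
over the analysis rows; binary indicator blocks left on their natural
scale. The complete-case sample is the intersection of rows valued by
every competing block and both outcomes; the achievable-N sample is each
block's own valued rows. Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1).
p-values are two-sided t; no multiple-testing correction (none is applied
in the source analyses). Exactly collinear block terms are dropped with a
diagnostic.

## 4. The difference-in-R² simulation

To ask whether an adjusted-R² gap of 0.01 between two competing indices is
larger than chance, each replicate draws (index₁, index₂, outcome) from a
trivariate normal in which both indices correlate √0.07 with the outcome
and ρ with each other, fits both single-predictor regressions at
n = 7,783, and records |R²₁ − R²₂|; the exceedance probability over
10,000 replicates is reported. The between-index correlation is the one
input the source leaves unstated; the package's default is ρ = 0.7,
chosen because competing cSES indices computed on the same respondents
are strongly correlated and because the delta-method analysis (implemented
in `delta_r2_normal_approx`, using the Pearson–Filon covariance of two
correlations sharing a variable) shows the exceedance probability is
driven almost entirely by this parameter. A sensitivity sweep over
ρ ∈ {0, 0.5, 0.7, 0.8, 0.9} is always emitted next to the point result;
at n = 7,783 it spans roughly 21% down to 0.02%. The probability is
two-sided (|ΔR²|); the analytic approximation is reported alongside for
every sweep point.

## 5. The synthetic cohort

The generator emulates the statistical structure of a large ageing-cohort
survey; its defaults are the package's study conditions.

* Three standard-normal capitals (social, financial, human) with
  correlations 0.25 (S–F), 0.15 (S–H), 0.45 (F–H) — financial–human
  strongest, matching the observed inter-scale association pattern. Each
  scale's two sub-factors share a fraction w of variance with their
  capital (w = 0.45 social, 0.60 financial; the financial pair couples
  more tightly, calibrated so the scales' internal consistencies land
  near the reported ≈ 0.6; instability enters with a negative sign).
* Items are probit-threshold indicators of their sub-factor. Default
  loadings are 0.80–0.85 for maternal-investment items, 0.45–0.70 for
  family structure (lived-with-grandparents loads −0.45: co-resident
  grandparents mark absent parents in this cohort's era), 0.70–0.80 for
  instability, 0.50–0.75 for average resources, and 0.15 for "mother
  worked" — deliberately below the 0.3 retention rule, so the pipeline
  reproduces the published decision to drop exactly one financial
  candidate. Thresholds are set from target marginal frequencies (e.g.
  8.9% never lived with father, 2.6% never with mother).
* Adult outcomes are linear in the latents: the depressive-tendency
  latent is −0.20·S − 0.12·H + 0.35·instability + 0.008·(age−70) + noise
  with **zero** coefficient on average financial resources — the
  generated null whose complete-case distortion Section 6 demonstrates —
  and the 8 symptom items are probit indicators of that latent (loading
  0.75), so the 0–8 sum score has realistic internal structure.
  Self-rated health (adult and childhood) is coded 1–5 with lower =
  better; education and height load mainly on human capital.
* The observation process: experimental-module items are administered to
  *nested* random subsamples (one uniform per respondent; an item is
  administered iff the uniform is below its module fraction — 22.1/22.1/
  20.1% maternal items, 2.4% number of parent figures and the 5-category
  self-rating, 2.3% bankruptcy and lost-business). Nesting reproduces the
  real survey's overlap structure, in which complete responders on a full
  item set number in the hundreds, not ~0 as independent per-item masking
  would imply. Core nonresponse rates per item match the reported
  coverage (e.g. father's occupation 66%, height 41%). Parental education
  is recorded continuously for ~62%, dichotomized for ~25%, missing
  otherwise, with the missing probability jumping from 0.10 to 0.55 when
  the respondent did not live with that parent. Finally the
  comparison-index components (parental education, father's occupation,
  3-level self-rating, moved-for-financial-reasons) receive extra masking
  with probability expit(logit(0.08) + 1.5·v), where the vulnerability
  score v weights low capitals (0.25), low average financial resources
  specifically (0.50) and high depressive tendency (0.60) — the
  mechanism by which complete-case analyses select against the socially
  vulnerable.
* One master seed expands through a spawned seed-sequence into six
  per-stage generators (latents, items, education, outcomes, covariates,
  missingness), so the missingness stage is reproducible independently of
  generation and identical configurations give byte-identical artifacts.

What the generator does **not** emulate: longitudinal waves and revisits,
proxy/exit interviews, census occupation coding (the six ordinal
categories are generated directly), survey weights, item response styles,
recall error correlated with age or cognition, and any non-normal latent
structure. Passing tests therefore show that the estimators recover the
model they assume under survey-realistic observation patterns — not that
the model is true of any real cohort.

## 6. The complete-case bias demonstration

With the null average-resources → depressive-symptoms effect and the
vulnerability-patterned masking above, rows surviving the complete-case
intersection are selected on (high resources, low depressive tendency)
jointly. Truncation on a sum induces a positive conditional association
between its oppositely-signed components, so among complete cases average
resources and depressive tendency correlate positively, and the
component-model coefficient of the average-resources factor score on the
symptom count comes out positive — a spurious "more resources, more
depression" association. The achievable-N analysis, which keeps every row
the validated measures can score, estimates the same coefficient within
sampling error of zero. The test suite checks the direction on a
three-seed battery at n = 10,000 (complete-case intersection ≈ 950 rows
per run), averaging over seeds to keep the Monte-Carlo noise of the
small complete-case samples below the effect.

## 7. Numerical choices and degenerate inputs

* Bivariate-normal rectangle probabilities via the SciPy multivariate
  normal CDF, cells floored at 1e-12; polychoric |ρ̂| > 0.9985 snapped to
  the 0.999 clamp.
* MAP optimization bounded to [−6, 6] per coordinate; residual variances
  floored at 0.02; category codes absent from the estimation margins are
  flagged and the respondent excluded from scale z-scoring.
* EM adds a 1e-8 ridge to observed-block covariances; all-missing rows
  are dropped with a log entry; an all-missing column is an error.
* z-scores use divisor n everywhere; zero variance is an error, never a
  silent NaN.
* Ties in factor labelling (which rotated factor is "maternal
  investment" etc.) are broken by total absolute loading; duplicate
  labels get numeric suffixes.
* Problem sizes in the test suite — recovery at n = 5,000, reliability at
  the default n = 31,169, the bias battery at n = 10,000 × 3 seeds, 50
  oracle tables and 100 oracle respondents — were chosen as the smallest
  scales at which the Monte-Carlo error of each check is comfortably
  below its tolerance.

## 8. Known limitations

* Scale-score standard errors downstream ignore the two-stage estimation
  (scores treated as data), consistent with the source analysis's own
  caution; no correction is attempted.
* The pair-weighted χ² is a pragmatic weighted-least-squares surrogate,
  not the full WLSMV statistic with mean-and-variance corrections; fit
  indices are validated structurally (perfect-fit, recovery, and
  calibration behaviour), not against any third-decimal published value.
* Single imputation understates education uncertainty by construction;
  multiple imputation with pooling is out of scope.
* The EM's multivariate-normality treats ordinal predictors as numeric
  dummies/codes; this is the standard PROC-MI-style approximation.
* Under heavy masking the polychoric matrix can need PSD repair; the
  repair magnitude is logged and large repairs should be treated as a
  data-quality warning, not silently trusted.
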