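# Methods

`traumameta` implements a pooled individual-participant analysis of acute and
persistent posttraumatic stress disorder (PTSD) and major depressive disorder
(MDD) after trauma, exercised end to end on a synthetic multi-study cohort
generator. This note documents the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic data do and do not
establish.

## Outcome definitions

PTSD is scored from the 17-symptom Clinician-Administered PTSD Scale (CAPS,
DSM-IV): severity is the sum of frequency (0–4) and intensity (0–4) over all
symptoms (range 0–136), with cluster severities for reexperiencing (B, items
1–5), avoidance (C, items 6–12) and hyperarousal (D, items 13–17). A symptom
counts as present when frequency ≥ 1 and intensity ≥ 2; the diagnosis
requires ≥ 1 B, ≥ 3 C and ≥ 2 D present symptoms. Duration and impairment
criteria are not evaluated — they were not collected consistently across the
cohorts this design emulates.

Probable MDD is BDI-II ≥ 20; in studies using the 7-item HADS depression
subscale, the score is first carried onto the BDI metric through the packaged
equating table, under which the threshold corresponds to HADS ≥ 13.

A participant assessed at 0–60 days (acute wave) and 122–456 days
(persistent wave) is labelled **Never** (no diagnosis at either wave),
**Acute** (wave 1 only) or **Persistent** (both waves). The
diagnosis-only-at-follow-up pattern, absent from the three-category scheme,
is labelled **Delayed** and excluded from the primary models (a merge-into-
Persistent option exists); a missing follow-up is **Unclassifiable** until
imputation resolves it. Both windows are closed intervals.

## IRT equating of the depression instruments

Unidimensionality is checked by ordinal confirmatory factor analysis:
polychoric correlations (two-step maximum likelihood; thresholds from the
margins, the latent correlation by maximizing the discretized bivariate-normal
likelihood with 48-node Gauss–Legendre quadrature per cell), then an
unweighted-least-squares factor fit. The discrepancy is the sum of squared
off-diagonal residuals, chi-square is `(n−1)·F`, and CFI/TLI/RMSEA use the
independence baseline. The conventional adequacy thresholds (CFI and TLI
above 0.95, RMSEA below 0.06) are what the test suite asserts on clean
one-factor data.

Each instrument (augmented with three CAPS-derived anchor items — the
depression-overlapping symptoms C4, D1, D3, recoded to 0–4 by binning
frequency+intensity as 0, 1–2, 3–4, 5–6, 7–8) is calibrated with a graded
response model fit by marginal maximum likelihood EM: 61 equally spaced
quadrature nodes on [−6, 6] with N(0,1) weights, per-item M-steps by L-BFGS
with analytic gradients on a log-discrimination/threshold-increment
parameterization, convergence when the largest parameter change falls below
1e−4 (cap 500 iterations). Standard errors come from the empirical Fisher
information of the marginal likelihood via the posterior-expected score
identity. Categories unobserved in the data are collapsed before fitting.

Linking uses the mean/sigma method on the pooled anchor *thresholds* (all
b-parameters of the three anchors, not item means): `A = SD_base/SD_target`,
`B = mean_base − A·mean_target`, applied as `b* = A·b + B`, `a* = a/A`. With
only three anchors, pooling all twelve thresholds stabilizes the SD ratio.

The total-score crosswalk is built by true-score equating: each integer
source score is inverted through the source test characteristic curve (TCC)
by bisection and mapped through the base TCC, rounded half-up; the endpoints
are pinned to the score-range extremes and monotonicity is enforced against
rounding ties. True-score and equipercentile equating coincide (within ±2
points) only when the two instruments have comparable reliabilities; with a
7-item versus a 21-item scale they genuinely diverge by several points in the
upper range, which is why the equipercentile oracle test pairs equal-length
instruments.

## Multiple imputation

Missing follow-up outcomes are imputed by chained equations on the long
(participant × wave) table, with fixed study dummies in every conditional
model and a participant-level random intercept for the two-level structure.

* Continuous severities: a linear model with participant random intercept and
  study-specific residual variances, fit in two moment-based stages (OLS →
  variance components from within-participant residual products and
  per-study residual variances → weighted refit). A full-ML mixed fit with
  heteroskedastic group residuals is not available in the installed stack;
  the two-stage estimator is deterministic, fast, and calibrates well in the
  coverage tests.
* Binary diagnoses (PTSD): a random-intercept probit fit by maximum
  likelihood with 15-node Gauss–Hermite quadrature; missing flags are drawn
  from posterior-predictive probabilities using empirical-Bayes participant
  intercepts.
* The probable-MDD flag is *by definition* a threshold on the equated
  severity, so it is derived deterministically from the completed severity
  rather than modelled — a probit on its own defining severity is perfectly
  separated.
* Parameter uncertainty: coefficients are drawn from their asymptotic normal
  distribution and residual variances from scaled chi-square draws before
  each imputation (normal-approximation FCS, not full Bayes).

Predictor sets are screened at |r| ≥ 0.10 with the index variable (study
dummies always retained), visited in order of increasing missingness, with
continuous variables first. If a conditional probit is quasi-separated the
strongest remaining predictor is dropped and the fit retried. Defaults:
m = 20 imputations, 10 cycles (the pipeline demo uses smaller values);
chain means per cycle are logged and their lag-1 autocorrelation reported as
a mixing diagnostic. Estimates are pooled by Rubin's rules with
Barnard–Rubin degrees of freedom.

## Risk-factor models

The primary model is a multinomial logit of trajectory class (Never as
reference; Acute, Persistent) on seven harmonized risk factors — age
(per year, centred at 38), female sex, single/not cohabiting, below-secondary
education, prior trauma (none / non-interpersonal / interpersonal, any
interpersonal exposure dominating), and index trauma (motor-vehicle accident
reference, other accident, assault) — plus fixed study dummies. Fitting is
Newton–Raphson on the exact likelihood with analytic Hessian; the
implementation matches `statsmodels.MNLogit` to machine precision in the
cross-check tests. A fit with any |coefficient| > 15 is flagged as suspected
separation and refit with a small ridge penalty.

Whether a risk factor acts differently on acute onset versus persistence is
tested by a likelihood-ratio test against the fit with that coefficient
constrained equal across the two outcome equations (the constraint is imposed
through a parameter-sharing map, so the constrained likelihood is maximized
directly; 1 df). Per-imputation chi-squares are combined by the D2
moment-based rule.

Persistence models restrict to Acute (0) versus Persistent (1) participants
and add acute symptom severities in three specifications: the other
disorder's severity (Model 1), both severities (Model 2), and depression
severity plus the three PTSD cluster severities (Model 3). Odds ratios are
reported per 5 points for depression and cluster severities and per 15
points for total PTSD severity; Wald CIs use pooled log-odds with
Barnard–Rubin df. Completed datasets missing an outcome class are excluded
from pooling and counted.

Descriptive tables report per-group N, percentages on each variable's
non-missing denominator within the group, and mean (SD), with Welch t-tests
(continuous) and Pearson chi-square (categorical) across the three observed
trajectory groups.

## Heterogeneity diagnostics

Calibration of the persistent-vs-rest model is assessed by bootstrap
out-of-bag evaluation: participants are resampled with replacement, the
model is fit in-bag, and the never-drawn participants (≈ 36.8% of the pool)
are predicted. Per study, the expected/observed ratio (Σp/Σy) and the Brier
score are accumulated and averaged over replicates, then over imputations.
Three model variants are available: fixed study dummies, a random study
intercept (Gauss–Hermite, 15 nodes; out-of-bag studies fall back from their
empirical-Bayes intercept to the population intercept), and a pooled model
with no study terms, which serves as the miscalibration baseline — a study
whose true intercept is shifted shows E/O below 1 only under a model that
cannot absorb the shift. Replicates whose in-bag sample has a single outcome
class are skipped and counted. Leave-one-study-out refits and a follow-up
window restriction (e.g., 270–456 days, re-deriving trajectories and
re-running imputation and models) complete the sensitivity set.

## Synthetic cohort generator

The generator emulates a five-study consortium: study sizes (1082, 118, 735,
155, 481), instruments (HADS in three studies, BDI in two), one critical-care
study restricted to motor-vehicle accidents, truncated-normal assessment days
with study-specific means/SDs, and study-specific follow-up rates
(59%–87%).

Trajectory classes per disorder are sampled **directly from a multinomial
logit** in the risk factors, so the generative log-odds are exactly the
estimands the models target; default effects are on the scale of the pooled
models' typical findings (female → persistent PTSD log-OR ln 2.14, assault
ln 1.78, accident deficits, small age effects). Comorbidity enters through a
Gaussian copula (default 0.6) on the two class draws, which leaves each
disorder's marginal class model intact — this is what makes the
parameter-recovery acceptance checks exact rather than approximate. Wave
correlation of the latent severities defaults to 0.7. Latent severities are
drawn on the side of the diagnosis threshold the class dictates (sequential
truncated normals preserving the wave correlation approximately), item
responses are drawn from the graded response model given the latent
severity, and a minimal projection (promoting or demoting the fewest
symptoms/points) makes re-scoring the items reproduce the intended diagnoses
exactly. Trajectory labels recovered from the item data therefore match the
generative truth exactly when no missingness is applied.

Item bank defaults: depression items use log-normal(0.5, 0.25)
discriminations and thresholds drawn from N(2.2, 1.3), placing the BDI-20
cut in the upper tail of the latent distribution (about the top 15%), as a
moderate-severity clinical cut-off sits in an acute-trauma population; with
easier items the cut lands mid-distribution and observed-score
classification of borderline cases degrades. CAPS rating scales use
log-normal(0, 0.3) discriminations with N(1.3, 0.9) thresholds, giving
acute-wave severity means near those of real acute cohorts; anchors get
discrimination 1.5 to stabilize linking.

Missingness removes wave-2 observed flags at per-study rates (1 − follow-up
rate), with extra depression-assessment loss (default 0.18) on top, under
MCAR or a MAR mechanism whose loss probability rises with wave-1 latent PTSD
severity (probit slope 0.8, recentred to hold the marginal rate). Wave-1
assessments are never removed. Which mechanism matches any real consortium
is unknowable from these data; both are provided.

**What the synthetic data do not establish.** The generator has no
continuous-time symptom process (classes are sampled, not evolved), no
item-level nonresponse within an observed instrument, no differential item
functioning across studies, and no time trend in persistence within the
follow-up window. Passing tests demonstrate that the estimators recover the
structures they assume — not that those structures hold in real cohorts.

## Numerical choices and edge cases

* Quadrature: 61 rectangular nodes on [−6, 6] (GRM); 15 Gauss–Hermite nodes
  (random intercepts); 48 Gauss–Legendre nodes per cell (polychoric).
* Multinomial/logistic Newton iterations use step-halving line search;
  convergence on gradient norm relative to |log-likelihood|.
* Crosswalk rounding is half-up with monotonicity enforcement; scores below
  the TCC floor clamp to the boundary.
* The bounded log-variance parameterization (log σ ∈ [−10, 2]) keeps the
  random-intercept optimizer finite; linear predictors are clipped at ±35
  before link evaluation.
* Degenerate inputs raise typed errors: constant items, single-class binary
  targets, empty trajectory groups, out-of-range scores and ratings, windows
  outside the admissible range.
* Determinism: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage seeds by hashing (master seed, stage name), and run
  manifests record artifact checksums. Identical configuration reproduces
  byte-identical artifacts.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to make Monte-Carlo error small
relative to their tolerances while keeping the default suite quick: OR
recovery uses 100 replicates of n = 5000 (fast generator path); Rubin
coverage 200 replicates of n = 120 with m = 8; the null-LRT calibration 500
simulations of n = 600; bootstrap calibration n = 3000 with B = 200; GRM
recovery n = 10,000. The pipeline demo runs the five studies at 10–12% scale
with m = 3–5 imputations.
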