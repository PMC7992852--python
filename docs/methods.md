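# Methods

## The activity–sleep index

Physical activity and sleep health are multi-dimensional behaviours, and
their joint pattern — not either behaviour alone — is what plausibly drives
mental-health change in combined interventions. The package summarises
twelve behaviour dimensions (six activity: MVPA session frequency,
resistance-training frequency, intensity, activity type, MVPA duration,
sitting; six sleep: daytime alertness, quality rating, timing, regularity,
efficiency, duration guideline) into a single composite. Each dimension is
min–max rescaled onto 0–10,

    score = ((x − x_min) / (x_max − x_min)) · n,        n = 10,

with the bounds taken over *all assessment points and both arms pooled*,
then oriented so that higher always means lower-risk behaviour
(dimensions where a higher raw value is riskier — sitting, sleepiness,
poor-quality rating, bed/wake variability — are flipped to `n − score`).
ASI-12 is the sum of all twelve (0–120); ASI-6 sums the subset
{RT frequency, MVPA duration, sitting, quality, efficiency, duration}
(0–60) for studies with sparser instruments.

Scoring decisions that were genuinely open and how they are fixed here:

* **Sleep timing** is a binary indicator of the sleep midpoint falling in
  the 02:00–04:00 window, rescaled like any other dimension (observed 0/1
  bounds make it 0-or-10). A graded distance-from-window variant is
  available via `derive_dimensions(..., timing_mode="graded")`. The binary
  reading is chosen because the dimension is defined by the window and a
  0/10 score is consistent with the means/SDs such a score produces.
* **Sleep duration** is a binary indicator of meeting the 7–9 h adult
  (18–64 y) guideline.
* **MVPA minutes** are truncated at 840 min/wk before scoring (the
  Active-Australia convention) so a single extreme recall cannot stretch
  the pooled bounds; configurable via `mvpa_cap`.
* **Partially missing profiles**: if any dimension is missing at a wave the
  wave's index is missing (`max_missing=0`). Pro-rating a sum over fewer
  dimensions would silently change what the index measures.
* **Degenerate bounds** (max = min, a constant dimension) score n/2 with a
  loud warning: the dimension carries no information, and a symmetric
  midpoint neither rewards nor penalises anyone.
* Bounds are pooled across trials by default (matching "over all assessment
  points"); per-trial bounds can be obtained by scoring each trial's frame
  separately with its own `compute_bounds`.

Because rescaling is affine and bounds are recomputed from the data, the
index is invariant to unit changes of any raw dimension; this is property-
tested.

## Mediation model

For mediator M (ASI-12 or ASI-6), outcome Y and wave w ∈ {3, 6} months:

* a-path: `M_w ~ group + M_0 + study`
* b and c′ jointly: `Y_w ~ group + M_w + M_0 + Y_0 + study` (default
  "table_footnote" covariate scheme; a "methods_text" variant drops `M_0`)
* total effect: `Y_w ~ group + Y_0 + study`
* mediated effect AB = a·b; proportion mediated = 100·AB/c, reported only
  when |c| > 1e−8 and flagged when AB and c disagree in sign (the ratio is
  meaningless near a null or inconsistent total effect).

`study` is an indicator for the second pooled trial: the trials are pooled
and adjusted for, not stratified. Under the "matched" scheme every model
shares the covariate set {M_0, Y_0, study}, and the OLS identity
c = c′ + a·b then holds to machine precision — this is used as an internal
correctness check, not as the reporting default. Path p-values are
large-sample z-tests (coefficient/SE) at α = 0.05.

### Bias-corrected bootstrap

The AB interval resamples whole participants with replacement (B = 5000 by
default), recomputes AB per resample, and applies the bias correction
z₀ = Φ⁻¹(fraction of resampled AB below the point estimate, ties counted
half): the interval endpoints are the empirical quantiles at
Φ(2z₀ ± z_{(1+γ)/2}). No acceleration constant is used (BC, not BCa).
Quantiles use the Hyndman–Fan type-6 rule (`numpy` method `"weibull"`),
the convention of several mainstream statistics packages; endpoints from
software using another quantile rule may differ in the last decimal.
Degenerate cases are defined rather than silent: B = 1 or an all-identical
bootstrap distribution yields a degenerate (v, v) interval with a warning,
and a distribution entirely on one side of the point estimate raises an
error advising a larger B. Known finite-sample behaviour, which the test
suite measures rather than assumes: the BC interval is close to nominal
when one path is null but the other is not (measured ≈7% exclusion at
n = 325), very conservative when both paths are null (≈0%), and its
coverage under a nonzero product runs a point or two below 95%.

### Missing data: FIML

Follow-up missingness is treated as missing at random given age and
baseline values. The FIML estimator models (M_0, Y_0, M_w, Y_w) as jointly
Gaussian with means linear in (intercept, group, study) and an unstructured
4×4 covariance, and maximises the observed-data likelihood by summing each
missingness pattern's marginal multivariate-normal log-density. The
maximiser is an EM algorithm over missingness patterns (monotone ascent,
no line-search failures; convergence when the relative log-likelihood
change is < 1e−10, with a hard iteration cap that raises on
non-convergence). Path coefficients are read off the implied conditional
regressions of the fitted joint distribution; with complete data the EM
M-step lands exactly on the multivariate-OLS MLE, so FIML equals
complete-case OLS identically — an acceptance-tested property. Standard
errors come from the numerically differentiated observed information in
(mean coefficients, log-Cholesky covariance) coordinates with a delta
method for the derived paths; they use the ML (divisor-n) covariance and so
sit slightly below the OLS small-sample SEs.

A structural fact worth knowing when interpreting FIML-vs-complete-case
comparisons: when whole waves are deleted jointly (mediator and outcome
together) and baselines are complete, the likelihood factorises and the
FIML b-path equals the complete-case b-path exactly; FIML's genuine
advantage appears in the a-path (whose model omits Y_0, a variable the
attrition depends on) and under item-level missingness, where participants
contribute partially observed waves.

### Exposure–mediator interaction

`interaction_check` augments the outcome model with a group×mediator
product term and reports its coefficient, SE and p-value; the mediation
model assumes this term is absent.

## Synthetic cohort generator

The generator emulates a pooled two-trial design: trial A 80/80
intervention/control, ages 18–54 (mean 41.5, SD 9.9); trial B 110/55, ages
45–64 (mean 52.0, SD 6.9); 81% female; 325 participants total, assessed at
0, 3 and 6 months. Baseline behaviour distributions describe physically
inactive adults with poor sleep (under 90 MVPA min/wk typical, sleep
quality ratings at the poor end, ~6.4 h sleep). Baseline outcome scales use
the pooled-sample means/SDs (e.g. depression 10.7 ± 8.1 on the doubled
DASS-21 scale, energy 44.7 ± 18.7).

Ground truth: the intervention effect `a_true` (default 3.0 ASI points) is
induced on the *raw* scales — extra MVPA minutes and sessions, fewer
sitting minutes, better quality ratings, longer sleep — so the generator
exercises the full derive→bounds→rescale→sum path. Because clipping,
rounding and data-driven bounds make the raw→ASI map mildly nonlinear, the
raw-shift multiplier is calibrated per realisation by a two-pass secant on
the fitted covariate-adjusted intervention coefficient; only the population
slope is calibrated, so the fitted a retains its natural sampling
variability. Follow-up outcomes are linear-Gaussian:

    Y_w = (1−γ)·μ + γ·Y_0 + c′·group + δ·study + b·(M_w − mean M_w) + ε,

with γ = 0.5, δ = 0 and per-outcome b and c′ defaulting to the fitted
3-month paths of the emulated analysis. Wave 6 carries wave-3 behaviour
forward with additional noise (no further structural dynamics). A latent
participant trait (stable wellbeing/behaviour propensity, SD 1) loads on
baseline behaviours, baseline outcomes and the follow-up behaviour
trajectory; it creates the baseline-outcome ↔ follow-up-behaviour
dependence that makes MAR attrition consequential rather than ignorable
for every model.

Attrition is logistic in age (−0.03/yr) and baseline depression (+0.03 per
point): younger, more-depressed participants drop out more, with
intercepts set for ≈85% completion at 3 months and ≈66% at 6 months,
monotone across waves by default. An `item_level` switch deletes the
behaviour instruments and the outcome questionnaires by independent draws,
emulating participants who return one survey but not the other. The
attrition strength is illustrative — the emulated trials report only its
direction — and the defaults were fixed from the reported completion
percentages before any testing.

What the generator does *not* emulate, hence what passing tests cannot
show about real data: outcome floors/ceilings (DASS values are unclipped
Gaussians, so the generator's scores can be negative where a real
instrument stops at 0 — a deliberate choice keeping the generative model
identical to the estimators' assumptions), item-level questionnaire
structure, practice/measurement-reactivity effects, non-Gaussian outcome
distributions, engagement-dependent dose–response, and any
missing-not-at-random mechanism.

## Problem sizes used by the test suite

Simulation-based checks run at the design's own size (n = 325) for
calibration/coverage (200 replicates, B = 500) and the FIML paired-bias
comparison (200 replicates), and at n = 5000 (200 replicates) for
large-sample parameter recovery; identities (decomposition, FIML = OLS)
use single cohorts. Tolerances are 3 Monte-Carlo standard errors for
recovery, binomial 3σ bands around nominal rates for
calibration/coverage, and 1e−10/1e−6 for algebraic and optimizer
identities respectively.

## Known limitations

* Proportion mediated is intrinsically unstable near a null total effect;
  the package floors and flags it but cannot make it interpretable there.
* The FIML observed-information SEs use finite differences; for
  ill-conditioned fits (tiny n, near-singular covariance) they can be
  returned as NaN rather than a misleading number.
* Severity banding assumes doubled (0–42) DASS-21 subscale scores; the
  threshold table is a JSON resource and can be replaced for the 0–21
  convention.
* The bootstrap resamples participants, not trials; with only two pooled
  studies a cluster bootstrap is not meaningful, and `study` enters as a
  fixed covariate.
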