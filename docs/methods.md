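# Methods

This note documents the statistical machinery in `mlas`, the modelling
choices that were genuinely open, and what the synthetic experiments do and
do not demonstrate.

## Data model

Patients are followed from listing (day 0) in integer days. Pre-transplant
analyses use daily counting-process rows `(t−1, t]` with the terminal event
(death, transplant, or censoring) flagged on the last row; risk sets are
unambiguous under this half-open convention, and a patient transplanted or
censored at day *t* is still part of the day-*t* death risk set. The
post-transplant analysis uses one record per transplanted patient, with
covariates measured at transplant (time-varying values carried forward).
Calendar dates appear only in I/O. Eligibility rules are data-driven
conjunctions of threshold comparisons; the two stock rules exclude patients
with panel reactive antibodies above 90% and group-D (restrictive) disease
with height under five feet — both groups face near-zero transplant
probability, and removing them protects the positivity assumption the
weights rely on.

## Selection weights

Transplant receipt and censoring are modelled as discrete-time daily hazards
by pooled logistic regression on the counting rows (statsmodels logit,
Newton). Denominator models condition on baseline covariates, geography and
current severity; numerator (stabilizer) models contain intercept and
flexible time-on-list terms only (restricted cubic spline, 4 knots at
equally spaced quantiles of person-days; hand-rolled Harrell basis).
Predicted probabilities are clipped to `[1e-10, 1−1e-10]`; a strict
positivity check is available and raises with the offending patient-day.

The daily stabilized weight multiplies, over days `s ≤ t`, the ratio of the
stabilized to the conditional probability of remaining untransplanted and
uncensored. The post-transplant weight is that cumulative ratio through the
day before transplant times the stabilized inverse probability of transplant
on the transplant day; a config switch (`include_tx_day`) drops the
transplant-day factor, since either convention appears in practice. Weights
are truncated at their 1st/99th percentiles by default (configurable,
bounds recorded on the output).

**Calibration diagnostics.** The mean stabilized weight among the at-risk
set at day *t* equals the ratio of counterfactual no-transplant survival to
naive (selection-blind) survival at *t*. It is therefore exactly 1 — the
usual rule of thumb — only when selection is orthogonal to mortality; under
informative selection the at-risk mean drifts below 1 even with perfectly
specified models. The calibration test accordingly uses a configuration
whose selection depends on geography only (which the death hazard ignores):
weights vary across patients, and the per-day at-risk means must be 1 within
3 standard errors at n = 5000.

## Weighted Cox estimation

The weighted partial likelihood with Breslow tie handling is maximized by
Newton–Raphson (gradient sup-norm < 1e-8, ≤ 100 iterations, ≤ 20
step-halvings). Covariates are centered internally; the weighted Breslow
cumulative baseline hazard is re-referenced to x = 0 and stored on the daily
grid with carry-forward between event days. Daily survival is
`S(t|x) = exp(−H0(t)·e^{xβ})`. An integer weight *k* is exactly equivalent
to duplicating the row *k* times, for both β and H0; tests enforce this to
1e-10, and unit-weight fits agree with independent reference
implementations (statsmodels PHReg with Breslow ties; lifelines on
ties-free data) to 1e-6. Monotone likelihoods (separation) are detected
both by coefficient divergence during iteration and by absurd coefficient
magnitude (>15) at a vanishing gradient, which is how separation actually
presents — the gradient dies on the likelihood plateau before the
coefficients stop growing. A robust sandwich covariance grouping score
residuals by patient is reported; it is descriptive only — interval
estimates downstream come from the bootstrap. Outcome models never include
follow-up time as a covariate.

## Scoring

Expected one-year waitlist and post-transplant days are the sums of the
daily survival probabilities. The raw benefit score `PT − 2·WL` lies in
[−730, 365] and is mapped affinely onto [0, 100] with
`100·(raw+730)/1095`; the constants follow from the raw score's bounds and
are configuration-exposed, since only the 0–100 range (not the map) is
fixed by the allocation system's description. Patients are eligible at an
offer date if listed, alive and not yet removed; ranking is by descending
score with ties broken by longer time since listing, then patient id — a
deterministic rule chosen for reproducibility. The "existing"-style
comparator is the identical pipeline with all weights set to 1, which
isolates exactly the effect of the selection weights (the published
allocation coefficients are proprietary to their registry and are not
reproduced here).

## Evaluation

*Time-dependent ROC.* Cumulative/dynamic ROC at horizon t*: cases are
events by t*, controls survivors past t*. Under censoring the bivariate
distribution of (marker, survival) is estimated with the Akritas
nearest-neighbor conditional Kaplan–Meier using a symmetric 0/1 kernel of
half-width `⌊λn⌋` on marker ranks (span default `λ = 0.25·n^{−0.20}`).
When no observation is censored at or before t* the empirical bivariate
distribution is used instead: smoothing exists only to handle censoring,
and the complete-data estimator makes the AUC *exactly* the Mann–Whitney
statistic of the marker against `1(T ≤ t*)` — a reduction the smoothed
estimator attains only approximately. The AUC is computed as the
(fractionally weighted) Mann–Whitney statistic, which equals the
trapezoidal area over the full threshold grid, ties handled by the ½
convention.

*Calibration.* Risk groups are tertiles of the linear predictor (boundary
ties to the lower-risk group); each group's mean predicted survival curve is
overlaid on the group's Kaplan–Meier estimate (lifelines; Greenwood
variance, log-log intervals) every 30 days.

*Bland–Altman.* Pairwise differences against pairwise means with limits at
±2 SD (n−1 denominator).

*Bootstrap.* The resampling unit is the patient — all of a patient's rows
move together and weights are re-estimated inside each replicate, so weight
estimation uncertainty propagates. Percentile CIs; the p-value of a model
difference uses the two-sided normal approximation with the bootstrap SD. A
degenerate comparison (identical pipelines) yields difference 0 and p = 1
by convention.

## Synthetic waitlist

The simulator emulates the selection structure that biases allocation
models. Baseline covariates: age ~ N(55, 10²) (standardized as
`age_s = (age−55)/10`), BMI ~ N(25, 4²), diagnosis groups A–D
(0.35/0.15/0.15/0.35), four regions, plus PRA and height for the
eligibility rules. A latent severity Z(t) follows a Gaussian random walk
(Z(0) ~ N(0,1), drift 0.002/day, step SD 0.08). Each day an active patient
faces competing logit-linear hazards of death, transplant and censoring
(death takes precedence within a day, then transplant); administrative
censoring at day 365. Transplanted patients draw a post-transplant death
day from a constant-baseline Cox law (`h0 = 4.5e-4`/day ≈ 85% one-year
survival at the reference) with known coefficients and a severity effect at
the transplant day. Rates were chosen to resemble a lung waitlist: daily
baseline transplant rate 3.5e-3 (most patients transplanted within a
year), death 6e-4, censoring 4e-4.

The counterfactual no-transplant outcome of *every* patient is generated
from the same severity path and the same uniform death draws with selection
switched off, so factual and counterfactual worlds agree up to removal
(counterfactual consistency); waitlist deaths occur on the same day in both.
The per-patient oracle survival curve is a Monte-Carlo average over severity
paths (closed form `(1−p)^t` when severity does not enter the death
hazard). All randomness descends from one seed through named
`SeedSequence` spawns.

Presets: `no_selection` (transplant/censoring independent of everything),
`paper_like` (moderate severity selection; geography enters selection
only), and `strong_selection` — transplant access decreasing in age
(−0.4), increasing in group-D disease (0.6), severity (0.6) and region
(±0.6, 0.3), with severity-dependent censoring (0.4). These effects are as
large as practical positivity allows: pushed further, sick patients are
selected near-deterministically, the implied inverse weights exceed what
any finite cohort can support, and the weighted estimand itself degrades —
the generative analogue of why positivity-threatened patients are excluded
from such analyses in the first place. `selection_strength` scales the
severity coefficients of the selection hazards.

In the replicate study the outcome models deliberately omit severity (it is
latent to them, as real allocation models omit relevant prognostic
information) and include the geography indicators, whose only association
with survival is the one selection induces — mirroring the role geography
plays in the weight models of the allocation literature.

## What the experiments show — and what they cannot

Under `strong_selection` (20 cohorts of n = 5000, fixed seeds):

* the naive one-year waitlist survival estimate is badly optimistic
  (observed mean predicted survival ≈ 0.13 above the counterfactual
  oracle); the weighted model cuts that bias by about half in every
  replicate — the calibration gain is the dominant, robust effect;
* the weighted pre-transplant model's one-year AUC against the
  counterfactual outcomes exceeds the unweighted model's *on average*
  (mean paired difference ≈ +0.002, ~4 SE above zero), but the
  per-replicate ordering is not deterministic: in this generative class
  selection distorts coefficients nearly proportionally, so ranking-based
  discrimination moves far less than calibration. Large per-replicate AUC
  gaps would require selection so strong that positivity — and with it the
  weighted estimator — breaks down first;
* the weighted post-transplant model recovers the generating coefficients
  with smaller mean absolute error than the unweighted fit, chiefly by
  removing the collider-induced spurious geography effects and the
  group-D attenuation. Individual coefficients can still benefit from
  luckily offsetting biases in the unweighted fit (non-collapsibility
  attenuation versus collider bias act in opposite directions for age).

The simulator does not model donor arrival, match runs, blood-group/size
compatibility, center-level queueing, or measurement error in covariates;
its severity process is a random walk rather than a clinically structured
trajectory. Passing these tests therefore demonstrates the correctness and
the qualitative behavior of the estimators under a known selection law, not
the real-world magnitude of any improvement.

## Problem sizes

The default test run uses cohorts of n = 5000 with 20 replicates for the
selection study, one n = 5000 cohort for weight calibration, and 200
mini-experiments × 200 bootstrap replicates for CI coverage.
`scripts/acceptance.py` uses the same sizes with 10 study replicates.
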