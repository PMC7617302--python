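# Methods

## The problem

Observational time-to-event analyses routinely face data imperfections — an
unmeasured prognostic factor, event times known only up to the clinic visit at
which they were detected — whose impact on the published estimate cannot be
assessed from the data alone. `survsim-qba` quantifies that impact by
*data-driven simulation*: it builds **oracle datasets** that keep the observed
covariate vectors and the observed outcome-time distribution but are, by
construction, free of the imperfection and governed by a known true model;
derives **imperfect datasets** by reintroducing the imperfection; analyses
both the same way; and summarizes bias, RMSE, coverage and power over `m`
Monte-Carlo repetitions. The contrast between oracle and imperfect summaries
is the expected impact of the imperfection on the real study's estimate.

## The permutational algorithm

The core generator reassigns the observed outcome times to the observed
subjects so that a user-specified proportional-hazards model
`HR_i(t) = exp(b_x x_i(t) + b_s s_i + Σ_c b_c c_i)` becomes the true
data-generating mechanism. Events are processed in increasing time order; the
event at time `t` goes to subject `i` of the current risk set with probability
`HR_i(t) / Σ_j HR_j(t)`, and the assignee leaves all later risk sets. Under a
proportional-hazards model this sequential weighted sampling is exactly the
conditional distribution of "who fails at `t` given someone fails at `t`", so
fitting the true model to the oracle data recovers the true coefficients; the
marginal outcome-time distribution is preserved exactly because the times
themselves are reused. With all log HRs at 0 the procedure reduces to a
uniform random permutation of outcomes — a property the tests check against
brute-force enumeration of the sequential sampling process on tiny cohorts.

Two risk-set conventions cover the two designs:

* **permute-all** (confounder study): every pooled outcome, event or
  censoring, is reassigned; after the events are placed, censoring times are
  matched uniformly at random, one-to-one, to the remaining subjects. The
  uniform matching follows the published permutational-algorithm literature.
* **fixed-censoring** (interval study): only events are assigned, and subject
  `i` is admissible for an event at `t` only while `i`'s original follow-up
  reaches `t` (this also guarantees a reporting visit at or after the event
  day exists); unassigned subjects keep their original follow-up end as
  censoring time.

Tied event times are processed in random order within the tie (the generator
shuffles before a stable sort) to avoid systematic ordering artifacts. Weights
are recomputed from the model at every event time; for a time-varying exposure
the panel value on the event day itself is used. Each repetition consumes one
seeded `numpy` generator in a fixed, documented order (confounder draw /
true-time draws, tie shuffle, sequential event draws, censoring matching), so
every repetition is reproducible from `(base_seed, scenario name, repetition)`
via `SeedSequence([base_seed, crc32(name), rep])`.

## Study 1 — unmeasured binary confounder

A binary prognostic factor (cancer stage III/IV in the motivating colon-cancer
analysis) is simulated from a logistic model
`P(S_i = 1) = expit(α + log(OR_x) x_i + Σ log(OR_c) c_i)`. The intercept `α`
is calibrated by monotone root-finding so the *cohort-average* probability —
the marginal prevalence, which is what a statement like "prevalence about
35%" refers to — hits the target to machine precision. The true hazard model
combines the scenario's exposure HR and stage HR (default 4.0) with the
covariate coefficients of the uncorrected Cox fit on the source data, so the
simulated world reproduces the empirical covariate-outcome structure. The
imperfect dataset is the oracle minus the stage column; both are analysed by
multivariable Cox fits (with/without stage).

The default scenario grid crosses exposure HR ∈ {1.0, 1.3, 1.5, 2.0}, stage
OR ∈ {1.0, 1.2, 2.0} and stage HR ∈ {1.0, 4.0} (eight rows, shipped in
`configs/confounder_table.yaml`). Two opposing mechanisms drive the imperfect
model's bias: *confounding* (stage associated with exposure and outcome)
pushes the exposure estimate up, while *noncollapsibility* of hazard ratios
(omitting a strong independent risk factor) pulls it toward the null; a null
exposure effect isolates the former, a null stage-exposure OR the latter.
Stage-covariate ORs default to zero and are configurable: the values used in
any real application should come from substantive knowledge about the actual
cohort, and the synthetic default deliberately keeps the confounding channel
through the exposure association only.

## Study 2 — interval-censored events with a time-varying exposure

Observed events are known only to lie in the `Δ_s`-day window ending at the
reporting visit `τ_s`. Each repetition draws a true day `T_s` uniformly on the
integers `{τ_s − Δ_s + 1, …, τ_s}`, assigns it by the permutational algorithm
with weights `exp(b_x X_i(T_s) + b_age age_i + b_male male_i)` (exposure from
the subject's daily panel on that day), and censors unassigned subjects at
their original follow-up end. The age/sex coefficients default to the
uncorrected midpoint-imputed fit on the observed data — which of the two
uncorrected fits supplies them is essentially immaterial, as both are close.
Age enters as a plain linear term in years; centering is omitted because
multiplicative constants cancel in the sampling probabilities and the fitting
backend normalises internally.

The assigned subject's own reporting interval (first visit at or after `T_s`,
and its predecessor or cohort entry) defines the imperfect versions: the
**midpoint** dataset imputes the event at `τ − Δ/2` (half-days rounded toward
the earlier day, clipped into the admissible window `[τ − Δ + 1, τ]` — the
clip only binds for one-day intervals, where the event day is known exactly),
the **endpoint** dataset at `τ` itself. All three datasets are analysed with
a counting-process Cox model in which each event's risk set uses the exposure
value in effect on the (true or imputed) event day. The misalignment between
the imputed day and the exposure actually driving the hazard is what produces
the systematic attenuation toward the null, stronger for endpoint than for
midpoint imputation.

A separate sensitivity analysis (`redistribution_analysis`) perturbs the
*observed* data only: each event is moved to a uniform random day in its own
interval, keeping its subject, and the model is refitted. Because no true
value is imposed, this probes only the variability attributable to unknown
event timing — not the bias — which is precisely the limitation of
QBA-style sensitivity analyses that the simulation framework overcomes.

## Estimation

All fits delegate to lifelines: `CoxPHFitter` for one-row-per-subject data,
`CoxTimeVaryingFitter` for start-stop data, both with Efron tie handling,
model-based SEs and Wald 95% CIs. The Newton-Raphson stopping rule is
tightened to a coefficient-step norm of 1e-9 so closed-form checks hold to
1e-6 or better. Non-converged or separated fits are flagged on the returned
record, logged, and excluded from summaries (pairwise for paired
comparisons), never silently dropped.

## Performance measures

For `m` converged estimates `θ̂_r` of truth `θ`: bias = mean − θ; relative
bias = 100·bias/θ (not applicable at θ = 0); empirical SE = sample SD (n−1);
RMSE = √(bias² + Var) with the same n−1 variance, so the identity
RMSE² = bias² + SE² is exact; coverage = fraction of 95% CIs containing θ;
rejection rate = fraction excluding 0 (type-I error at θ = 0, power
otherwise). Monte-Carlo SEs: SE/√m for bias, binomial √(p(1−p)/m) for
proportions. Paired comparisons report bias and RMSE ratios and the
percentage of repetitions in which one model's estimate is strictly closer to
the truth (ties count as not closer; with continuous estimates ties have
probability ≈ 0).

Replication-count planning uses the normal approximation: with a true bias of
`f` empirical SEs, the bias test rejects with probability
`Φ(f√m − z₀.₉₇₅) + Φ(−f√m − z₀.₉₇₅)`; `m = 1000` gives 0.885 for `f = 0.1`,
and the smallest `m` reaching 90% power is 1051.

## Synthetic cohorts

The fixture generators emulate the *structure* of the two motivating studies,
not any real records:

* **colon-like** (defaults: n = 906, 19.3% exposed, 441/906 events): nine
  mixed-type covariates from a Gaussian copula (four thresholded to binary),
  exposure from a logistic model with calibrated intercept, event times
  exponential in the covariates with uniform administrative censoring whose
  baseline rate is solved analytically so the expected event fraction hits
  the target.
* **benzo-like** (defaults: n = 1250, follow-up up to 1095 days, 22.8%
  events): per-subject visit schedules with gamma between-visit intervals
  moment-matched to mean 92.2 days and SD 17.8 (IQR 80–104); prescription
  episodes alternating geometric on/off durations (means 60/90 days, supply
  starting day 1 per the new-user design); the daily exposure indicator is
  "any supplied day within the day itself plus the previous 14 days", so
  exposure persists 14 days past an episode's end; events marked at a random
  visit of a randomly chosen ~22.8% of subjects, independently of exposure.
  Follow-up intentions are uniform between 120 days and the maximum, giving a
  realistic spread of censoring times. Age ~ Normal(75, 6) folded above 66;
  40% male (placeholders where the source publications give no values).

In both generators the outcome process is independent of exposure given the
covariates: the association under study is injected afterwards by the
permutational algorithm, mirroring the framework's own logic. What passing
tests on these fixtures demonstrates is that the *machinery* (calibration,
assignment, imputation, estimation, summarization) is correct at realistic
scale; they do not reproduce the real datasets' covariate effects, visit
irregularities, or prescription patterns, so numeric results on fixtures are
not estimates for the real studies.

## Problem sizes and numerical choices

The reduced-scale validation runs (test suite and `scripts/acceptance.py`)
use m = 200 repetitions per scenario: the confounder study at full fixture
scale (n = 906), the interval study on a reduced cohort (n = 450, follow-up
≤ 730 days) — sizes chosen so a complete validation pass stays in the
minutes range while keeping Monte-Carlo SEs of bias below ~0.01. Full-scale
runs (m = 1000, the shipped YAML configs) reproduce the framework's intended
operating point. Other numerical choices: intercept calibration by `brentq`
on [−40, 40] with 1e-10 tolerance; integer event days throughout the
interval study (the panels' granularity); weights validated finite and
positive at every draw; an empty risk set raises immediately rather than
silently re-using subjects.

## Known limitations

No competing risks, recurrent events, left truncation, stratified or
time-dependent-coefficient Cox models; no interval-censoring likelihood
estimators (the imputation strategies under study are the point); no
probabilistic sampling of bias parameters (scenario values are fixed); the
permutational algorithm reuses observed times by design and cannot
extrapolate beyond the observed follow-up.
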