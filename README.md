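# survsim-qba

Data-driven simulations for **quantitative bias analysis (QBA)** in
multivariable time-to-event studies.

Most observational survival analyses carry a known imperfection — an important
prognostic factor that was never measured, or event times known only up to the
clinic visit at which they were detected. `survsim-qba` quantifies what that
imperfection is expected to do to the study's estimate. It builds **oracle
datasets** that are free of the imperfection but keep the real data's
covariate vectors and outcome-time distribution, derives **imperfect
datasets** by reintroducing the imperfection, analyses both identically with
Cox proportional-hazards models, and summarizes bias, RMSE, CI coverage and
power over *m* Monte-Carlo repetitions. It is written for epidemiologists and
biostatisticians who want sensitivity analyses that report *bias against a
known truth* rather than only variability.

## The core algorithm

Oracle data are produced by the **permutational algorithm**: observed outcome
times are reassigned to observed subjects so that a user-chosen
proportional-hazards model

&nbsp;&nbsp;&nbsp;&nbsp;HR<sub>i</sub>(t) = exp( β<sub>x</sub> x<sub>i</sub>(t) + β<sub>s</sub> s<sub>i</sub> + Σ<sub>c</sub> β<sub>c</sub> c<sub>i</sub> )

becomes the true data-generating mechanism. Outcomes are processed in
increasing time order; the event at time *t* is assigned to one subject of the
current risk set with probability HR<sub>i</sub>(t) / Σ<sub>j</sub> HR<sub>j</sub>(t),
censoring times are assigned uniformly at random from the same risk set, and
every assignee leaves all later risk sets. The exposure may be a daily
time-varying indicator (looked up in each subject's panel on the event day).

Two ready-made study designs sit on top:

* `ConfounderBiasStudy` — simulates an unmeasured binary confounder from a
  calibrated logistic model, generates oracles that include it, and contrasts
  Cox fits with and without it (separating confounding bias from the
  noncollapsibility of hazard ratios);
* `IntervalCensoringStudy` — draws true event days inside observed
  between-visit intervals, assigns them against daily exposure panels, and
  contrasts fits at the true days with midpoint- and endpoint-imputed days.

Synthetic cohort generators (`make_colon_like`, `make_benzo_like`) reproduce
the structure of a cancer prognostic cohort and of a new-user
pharmacoepidemiologic cohort, so the whole pipeline runs without any external
data.

## Worked example

```python
import numpy as np
import survsim_qba as sq

data = sq.make_colon_like(sq.ColonLikeSpec(), np.random.default_rng(7))
scenarios = [
    sq.Scenario(name="null", true_hr_exposure=1.0,
                confounder=sq.ConfounderSpec(or_exposure=1.2, hr_outcome=4.0)),
    sq.Scenario(name="hr1.3", true_hr_exposure=1.3,
                confounder=sq.ConfounderSpec(or_exposure=1.2, hr_outcome=4.0)),
]
study = sq.ConfounderBiasStudy.from_dataframe(data.frame, scenarios, m=50)
rec = study.baseline()
print(f"uncorrected HR = {rec.hr:.3f} (95% CI {np.exp(rec.ci_low):.3f}-{np.exp(rec.ci_high):.3f})")
print(study.fit(base_seed=1).summary())
```

prints

```
uncorrected HR = 1.039 (95% CI 0.826-1.308)
Quantitative bias analysis — Monte-Carlo performance (log HR scale)

scenario         model  true_log_hr  m_used     bias  relative_bias_pct  empirical_se     rmse  coverage  rejection_rate
    null        oracle        0.000      50   -0.006                NaN         0.116    0.116     0.960           0.040
    null no_confounder        0.000      50    0.060                NaN         0.117    0.132     0.900           0.100
   hr1.3        oracle        0.262      50    0.032             12.038         0.104    0.109     0.940           0.760
   hr1.3 no_confounder        0.262      50    0.038             14.608         0.103    0.110     0.960           0.760
```

Reading the table: each row is one analysis model in one scenario. The
`oracle` model (adjusting for the simulated stage variable) is unbiased and
covers at ~95%, which validates the generation machinery. In the `null`
scenario the `no_confounder` model — the one a real analyst would be forced to
fit — overestimates the exposure log HR by 0.060 and its type-I error rate
rises to 10%: that is the expected footprint of confounding by the omitted
factor. With a weak stage-exposure association (OR 1.2) and a true HR of 1.3,
confounding and noncollapsibility nearly cancel (bias 0.038 vs 0.032). A real
analysis would use m = 1000 repetitions (see `configs/`); m = 50 keeps the
example quick.

The same pattern works for the interval-censoring design
(`IntervalCensoringStudy`, `make_benzo_like`, `table2_scenarios`), whose
`fit()` additionally reports paired midpoint-vs-endpoint comparisons, and
which offers `redistribution_analysis()` — a QBA-style perturbation of the
observed data that demonstrates why redistributing event times cannot reveal
the attenuation bias the simulations quantify.

## Command line

```bash
survsim-qba make-fixture --spec colon --out fixtures/ --seed 7
survsim-qba baseline --config configs/confounder_table.yaml
survsim-qba run --config configs/confounder_table.yaml
```

`run` writes `summary.csv` (one row per scenario × model), `estimates.csv`
(per-repetition estimates) and `provenance.json` (seeds, config hash,
version) to the configured output directory.

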