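# Four-scenario grid for the interval-censoring study: true hazard ratio of
# the time-varying exposure in {1.0, 1.5, 2.0, 2.5}.
# Run with: survsim-qba run --config configs/interval_table.yaml
study: interval
fixture: {kind: benzo, seed: 13}
m: 1000
base_seed: 1
out: results/interval
scenarios:
  - {name: hr1.0, true_hr_exposure: 1.0}
  - {name: hr1.5, true_hr_exposure: 1.5}
  - {name: hr2.0, true_hr_exposure: 2.0}
  - {name: hr2.5, true_hr_exposure: 2.5}
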