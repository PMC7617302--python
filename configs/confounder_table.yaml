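# Eight-scenario grid for the unmeasured-confounder study: true exposure HR,
# confounder-exposure odds ratio, confounder-outcome hazard ratio.
# Run with: survsim-qba run --config configs/confounder_table.yaml
study: confounder
fixture: {kind: colon, seed: 7}
m: 1000
base_seed: 1
out: results/confounder
scenarios:
  - {name: s1, true_hr_exposure: 1.0, stage_or_exposure: 1.2, stage_hr: 4.0}
  - {name: s2, true_hr_exposure: 1.3, stage_or_exposure: 1.2, stage_hr: 4.0}
  - {name: s3, true_hr_exposure: 1.5, stage_or_exposure: 1.2, stage_hr: 4.0}
  - {name: s4, true_hr_exposure: 2.0, stage_or_exposure: 1.2, stage_hr: 4.0}
  - {name: s5, true_hr_exposure: 1.3, stage_or_exposure: 1.0, stage_hr: 4.0}
  - {name: s6, true_hr_exposure: 1.0, stage_or_exposure: 2.0, stage_hr: 4.0}
  - {name: s7, true_hr_exposure: 1.3, stage_or_exposure: 2.0, stage_hr: 4.0}
  - {name: s8, true_hr_exposure: 1.3, stage_or_exposure: 1.0, stage_hr: 1.0}
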