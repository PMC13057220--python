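# Desk-scale experiment: three organs, file-driven, reproducible.
# Run with: organ-age run --config examples/experiment.yaml --out-dir report/
schema_version: 1
seed: 7
n_subjects: 150
organs: [brain, kidney_left, kidney_right]
margin: 4
target_grid: [32, 32, 32]

train:
  epochs: 8
  batch_size: 16
  learning_rate: 0.003
  split_ratio: 0.8
  channels: [8, 16, 32]

# hazards, demographics, factors and phantom geometry keep their defaults;
# override any of them here, e.g.:
# hazards:
#   ckd:
#     baseline_rate: 0.004
#     log_hr_per_pag_year: 0.17
#     source_organ: kidney_left
#     disease_acceleration: 3.0
#     affected_organs: [kidney_left, kidney_right]

survival_outcomes: [ckd, alzheimers]
make_figures: true
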