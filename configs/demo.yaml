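# Demo pipeline: fully synthetic 200-subject cohort, all stages.
seed: 7
out_dir: runs/demo

simulate:
  n_subjects: 200
  recording_duration: 15.0

select:
  n_keep: 30

models:
  classifiers: [svc, knn, rf]
  regressors: [knn, svr, lightgbm]
  stacking: true

evaluate:
  by_age_group: true
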