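# Demo run: a 300-sample synthetic cohort with one planted prognostic
# feature (HR 3.5) among 199 nulls, screened over 50 random splits.
seed: 7
outdir: survscreen_demo
simulate:
  cohort:
    n_samples: 300
    n_features: 200
    n_prognostic: 1
  knockdown:
    n_genes: 500
    n_affected: 50
screen:
  n_iterations: 50
  p_threshold: 0.001
fdr:
  frequency_cutoff: 0.5
utility:
  horizon_days: 1826.25
  models:
    - [stage, grade]
    - [stage, grade, marker]
signature:
  fold_change_cutoff: 1.25
  r_threshold: 0.15
  pseudocount: 0.01
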