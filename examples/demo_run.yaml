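# Demo pipeline configuration for `coxmediate analyze --config examples/demo_run.yaml --out <dir>`.
# Omitted simulation keys fall back to the packaged calibration defaults
# (glucose 92/97 mg/dl, insulin 5.5/9.8 uIU/ml, ~5-8% incidence over 16 y).
seed: 2017
outcome: breast
simulation:
  n_subjects: 4000
  baseline_rate: 0.004   # raised above the default so the demo has ample events
snps: [rs560887, rs780094]
mediators: [glucose, homa_ir]
covariates: [age, education_high]
strata: [bmi]
n_boot: 200
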