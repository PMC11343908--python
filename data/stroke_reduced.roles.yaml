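outcome: case
riskfactors:
  exercise: 0
  high_blood_pressure: 0
  smoking: 0
  stress: 0
  diabetes: 0
  early_stage_heart_disease: 0
weights: weights
strata: strata
time: time
event: event
categorical: [region, alcohol, education]
covariates: [region, sex, age, education]
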