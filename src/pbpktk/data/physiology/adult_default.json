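{
 "name": "adult_default",
 "body_weight_kg": 70.0,
 "cardiac_output_L_per_h": 348.0,
 "alveolar_ventilation_L_per_h": 300.0,
 "volume_fractions": {
  "blood": 0.079,
  "fat": 0.19,
  "skin": 0.037,
  "kidney": 0.0044,
  "liver": 0.026,
  "rapid": 0.05,
  "slow": 0.6
 },
 "flow_fractions": {
  "fat": 0.05,
  "skin": 0.058,
  "kidney": 0.19,
  "liver": 0.24,
  "rapid": 0.33,
  "slow": 0.132
 },
 "citation": "Reference adult physiology (70 kg) with tissue volumes and perfusion fractions in the Ramsey-Andersen human PBPK convention (ICRP/Brown et al. 1997 compilation)."
}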