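{
 "model": "mehg",
 "absorption_fraction": 0.95,
 "rates_per_day": {
  "blood": {
   "liver": 0.6,
   "kidney": 0.08,
   "brain": 0.06,
   "hair": 0.0053,
   "urine": 0.0008
  },
  "liver": {
   "blood": 0.3,
   "feces": 0.004
  },
  "kidney": {
   "blood": 0.1,
   "urine": 0.0015
  },
  "brain": {
   "blood": 0.025
  }
 },
 "hair_growth_g_per_day": 0.35,
 "citation": "Linear first-order methylmercury toxicokinetics patterned after Carrier et al. (2001): blood, liver, kidney, brain, hair, urine, feces; predominantly fecal elimination, whole-body half-life on the order of 50 days."
}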