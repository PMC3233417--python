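{
 "model": "arsenic",
 "species": [
  "AsV",
  "AsIII",
  "MMA",
  "DMA"
 ],
 "tissues": [
  "lung",
  "liver",
  "gi",
  "kidney",
  "muscle",
  "brain",
  "skin",
  "heart"
 ],
 "body_weight_kg": 70.0,
 "cardiac_output_L_per_h": 348.0,
 "blood_volume_fraction": 0.079,
 "volume_fractions": {
  "lung": 0.008,
  "liver": 0.026,
  "gi": 0.017,
  "kidney": 0.0044,
  "muscle": 0.4,
  "brain": 0.02,
  "skin": 0.037,
  "heart": 0.005
 },
 "flow_fractions": {
  "lung": 0.03,
  "liver": 0.24,
  "gi": 0.16,
  "kidney": 0.19,
  "muscle": 0.22,
  "brain": 0.12,
  "skin": 0.02,
  "heart": 0.02
 },
 "partitions": {
  "AsV": {
   "lung": 1.0,
   "liver": 2.0,
   "gi": 2.0,
   "kidney": 3.0,
   "muscle": 0.8,
   "brain": 0.8,
   "skin": 1.5,
   "heart": 1.0
  },
  "AsIII": {
   "lung": 1.5,
   "liver": 5.0,
   "gi": 3.0,
   "kidney": 4.0,
   "muscle": 1.0,
   "brain": 1.0,
   "skin": 2.5,
   "heart": 1.2
  },
  "MMA": {
   "lung": 1.0,
   "liver": 2.0,
   "gi": 2.0,
   "kidney": 3.0,
   "muscle": 0.8,
   "brain": 0.5,
   "skin": 1.5,
   "heart": 1.0
  },
  "DMA": {
   "lung": 1.0,
   "liver": 2.0,
   "gi": 2.0,
   "kidney": 2.0,
   "muscle": 0.8,
   "brain": 0.5,
   "skin": 1.5,
   "heart": 1.0
  }
 },
 "reduction_per_h": {
  "liver": 1.0,
  "kidney": 0.8
 },
 "oxidation_per_h": {
  "liver": 0.3,
  "kidney": 0.3
 },
 "methylation": {
  "AsIII_to_MMA": {
   "vmax_ug_per_h": 20.0,
   "km_ug_per_L": 100.0
  },
  "MMA_to_DMA": {
   "vmax_ug_per_h": 30.0,
   "km_ug_per_L": 150.0
  }
 },
 "urinary_clearance_L_per_h": {
  "AsV": 3.0,
  "AsIII": 0.5,
  "MMA": 2.0,
  "DMA": 4.0
 },
 "oral_ka_per_h": 0.5,
 "gut_to_feces_per_h": 0.02,
 "citation": "Multi-species human arsenic PBPK structure patterned after El-Masri and Kenyon (2008): interconnected As(V)/As(III)/MMA/DMA sub-models, hepatic Michaelis-Menten methylation, species-specific renal clearance. Rate constants are approximate transcriptions."
}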