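{
 "chemical": "VC",
 "name": "vinyl chloride",
 "molecular_weight_g_per_mol": 62.5,
 "blood_air_partition": 1.16,
 "tissue_blood_partitions": {
  "fat": 17.0,
  "kidney": 1.0,
  "liver": 1.2,
  "rapid": 1.2,
  "slow": 0.83
 },
 "vmax_c_mg_per_h_kg075": 4.0,
 "km_mg_per_L": 0.1,
 "k_first_order_per_h": 0.0,
 "oral_ka_per_h": 1.0,
 "dermal_kp_cm_per_h": null,
 "skin_water_partition": null,
 "citation": "Human VC PBPK parameterization after Clewell et al. (2001)."
}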