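{
 "chemical": "DCM",
 "name": "dichloromethane",
 "molecular_weight_g_per_mol": 84.93,
 "blood_air_partition": 9.7,
 "tissue_blood_partitions": {
  "fat": 12.4,
  "kidney": 1.0,
  "liver": 1.46,
  "rapid": 1.46,
  "slow": 0.82
 },
 "vmax_c_mg_per_h_kg075": 4.0,
 "km_mg_per_L": 0.4,
 "k_first_order_per_h": 1.0,
 "oral_ka_per_h": 1.0,
 "dermal_kp_cm_per_h": null,
 "skin_water_partition": null,
 "citation": "Human DCM PBPK parameterization after Andersen et al. (1987, 1991): saturable CYP2E1 oxidation plus first-order GST pathway."
}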