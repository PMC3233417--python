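{
 "chemical": "CCl4",
 "name": "carbon tetrachloride",
 "molecular_weight_g_per_mol": 153.82,
 "blood_air_partition": 2.64,
 "tissue_blood_partitions": {
  "fat": 136.0,
  "kidney": 4.0,
  "liver": 5.4,
  "rapid": 5.4,
  "slow": 1.6
 },
 "vmax_c_mg_per_h_kg075": 0.4,
 "km_mg_per_L": 0.25,
 "k_first_order_per_h": 0.0,
 "oral_ka_per_h": 1.0,
 "dermal_kp_cm_per_h": null,
 "skin_water_partition": null,
 "citation": "Human CCl4 PBPK parameterization after Paustenbach et al. (1988) / Thrall et al. (2000) lineage."
}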