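{
 "chemical": "BEN",
 "name": "benzene",
 "molecular_weight_g_per_mol": 78.11,
 "blood_air_partition": 8.19,
 "tissue_blood_partitions": {
  "fat": 54.9,
  "kidney": 2.0,
  "liver": 2.95,
  "rapid": 2.95,
  "slow": 1.37
 },
 "vmax_c_mg_per_h_kg075": 2.11,
 "km_mg_per_L": 0.35,
 "k_first_order_per_h": 0.0,
 "oral_ka_per_h": 1.0,
 "dermal_kp_cm_per_h": null,
 "skin_water_partition": null,
 "citation": "Human benzene PBPK parameterization after Brown et al. (1998) / Bois et al. (1996) lineage; partitions from human blood:air and tissue:air measurements (Fiserova-Bergerova)."
}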