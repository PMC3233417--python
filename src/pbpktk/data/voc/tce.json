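{
 "chemical": "TCE",
 "name": "trichloroethylene",
 "molecular_weight_g_per_mol": 131.39,
 "blood_air_partition": 9.2,
 "tissue_blood_partitions": {
  "fat": 58.6,
  "skin": 2.0,
  "kidney": 1.5,
  "liver": 5.0,
  "rapid": 5.0,
  "slow": 2.0
 },
 "vmax_c_mg_per_h_kg075": 7.44,
 "km_mg_per_L": 1.39,
 "k_first_order_per_h": 0.0,
 "oral_ka_per_h": 1.0,
 "dermal_kp_cm_per_h": 0.012,
 "skin_water_partition": 6.4,
 "citation": "Human TCE PBPK parameterization after Fisher et al. (1998), adult male; measured human skin:blood partition; dermal permeability from Poet et al. (2000)."
}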