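{
 "chemical": "PCE",
 "name": "perchloroethylene",
 "molecular_weight_g_per_mol": 165.83,
 "blood_air_partition": 10.3,
 "tissue_blood_partitions": {
  "fat": 125.0,
  "skin": 5.1,
  "kidney": 5.0,
  "liver": 6.1,
  "rapid": 6.1,
  "slow": 2.7
 },
 "vmax_c_mg_per_h_kg075": 0.18,
 "km_mg_per_L": 4.0,
 "k_first_order_per_h": 0.0,
 "oral_ka_per_h": 1.0,
 "dermal_kp_cm_per_h": null,
 "skin_water_partition": null,
 "citation": "Human PCE PBPK parameterization after Gearhart et al. (1993) / Covington et al. lineage; measured human skin:blood partition."
}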