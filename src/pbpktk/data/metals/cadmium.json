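{
 "model": "cadmium",
 "absorption_fraction": {
  "male": 0.05,
  "female": 0.1
 },
 "transfers_per_day": {
  "plasma": {
   "liver": 0.3,
   "kidney": 0.05,
   "other": 0.25,
   "rbc": 0.05,
   "urine": 0.0002,
   "feces": 0.1
  },
  "rbc": {
   "plasma": 0.01
  },
  "liver": {
   "blood_mt": 0.00025,
   "feces": 5e-05
  },
  "other": {
   "blood_mt": 5e-05
  },
  "blood_mt": {
   "kidney": 0.12,
   "plasma": 0.12,
   "urine": 0.005
  },
  "kidney": {
   "urine": 0.00011,
   "blood_mt": 5e-05
  }
 },
 "growth": {
  "male": {
   "ages": [
    0,
    1,
    5,
    10,
    15,
    20,
    25,
    90
   ],
   "bw_kg": [
    3.5,
    10,
    18,
    32,
    60,
    75,
    78,
    78
   ]
  },
  "female": {
   "ages": [
    0,
    1,
    5,
    10,
    15,
    20,
    25,
    90
   ],
   "bw_kg": [
    3.4,
    9.5,
    17.5,
    33,
    54,
    62,
    65,
    65
   ]
  }
 },
 "organ_weight_fractions": {
  "kidney": {
   "ages": [
    0,
    10,
    20,
    90
   ],
   "fraction": [
    0.0075,
    0.005,
    0.0044,
    0.0042
   ]
  },
  "liver": {
   "ages": [
    0,
    10,
    20,
    90
   ],
   "fraction": [
    0.04,
    0.03,
    0.026,
    0.025
   ]
  }
 },
 "creatinine_mg_per_kg_day": {
  "male": {
   "ages": [
    0,
    10,
    18,
    90
   ],
   "value": [
    8,
    18,
    23,
    23
   ]
  },
  "female": {
   "ages": [
    0,
    10,
    18,
    90
   ],
   "value": [
    7,
    15,
    18,
    18
   ]
  }
 },
 "max_age_years": 90,
 "citation": "Daily-step cadmium toxicokinetics in the Nordberg-Kjellstrom lineage as modified by Choudhury et al. (2001) / Diamond et al. (2003); coefficients transcribed to reproduce the lineage's documented organ burdens and kinetics (GI absorption 5%/10% male/female, hepatic Cd-MT release routed to kidney, kidney turnover half-life ~12 y)."
}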