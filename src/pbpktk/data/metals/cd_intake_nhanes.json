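{
 "male": {
  "age_groups": [
   [
    6,
    11
   ],
   [
    12,
    19
   ],
   [
    20,
    39
   ],
   [
    40,
    59
   ],
   [
    60,
    90
   ]
  ],
  "intake_ug_per_day": [
   15.0,
   19.7,
   22.4,
   22.1,
   17.6
  ]
 },
 "female": {
  "age_groups": [
   [
    6,
    11
   ],
   [
    12,
    19
   ],
   [
    20,
    39
   ],
   [
    40,
    59
   ],
   [
    60,
    90
   ]
  ],
  "intake_ug_per_day": [
   13.5,
   15.1,
   16.2,
   16.5,
   14.4
  ]
 },
 "note": "Geometric-mean dietary cadmium intakes by sex and age stratum (NHANES 2003-2004 dietary estimates, after Choudhury et al. 2001); ages below 6 use the 6-11 stratum value."
}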