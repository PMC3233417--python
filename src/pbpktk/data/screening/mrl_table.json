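{
 "entries": [
  {
   "chemical": "BEN",
   "inhalation_ppm": 0.003,
   "oral_mg_per_kg_day": 0.0005,
   "duration_class": "chronic"
  },
  {
   "chemical": "CCl4",
   "inhalation_ppm": 0.03,
   "oral_mg_per_kg_day": 0.007,
   "duration_class": "intermediate"
  },
  {
   "chemical": "DCM",
   "inhalation_ppm": 0.6,
   "oral_mg_per_kg_day": 0.2,
   "duration_class": "acute"
  },
  {
   "chemical": "PCE",
   "inhalation_ppm": 0.3,
   "oral_mg_per_kg_day": 0.06,
   "duration_class": "chronic"
  },
  {
   "chemical": "TCE",
   "inhalation_ppm": 0.2,
   "oral_mg_per_kg_day": 0.05,
   "duration_class": "acute"
  },
  {
   "chemical": "VC",
   "inhalation_ppm": 2.0,
   "oral_mg_per_kg_day": 0.2,
   "duration_class": "acute"
  }
 ],
 "note": "ATSDR Minimal Risk Levels used for the VOC screening scenarios: continuous 24 h/day inhalation at the ppm MRL plus the oral MRL split into 4 daily drinking bouts."
}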