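analyte,statistic,value,ci_low,ci_high,lod,unit,stratum
BEN,95th percentile,0.260,0.210,0.320,0.024,ng/mL,US population
CCl4,<LOD,,,,0.005,ng/mL,US population
DCM,<LOD,,,,0.07,ng/mL,US population
PCE,95th percentile,0.140,0.091,0.300,0.048,ng/mL,US population
TCE,<LOD,,,,0.012,ng/mL,US population
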