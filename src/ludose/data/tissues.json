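{
 "soft_tissue_icrp": {
  "density_g_cm3": 1.0,
  "mass_fractions": {
   "H": 0.10447,
   "C": 0.23219,
   "N": 0.02488,
   "O": 0.63032,
   "Na": 0.00113,
   "Mg": 0.00013,
   "P": 0.00133,
   "S": 0.00199,
   "Cl": 0.00134,
   "K": 0.00199,
   "Ca": 0.00023
  }
 },
 "cortical_bone_icrp": {
  "density_g_cm3": 1.85,
  "mass_fractions": {
   "H": 0.034,
   "C": 0.155,
   "N": 0.042,
   "O": 0.435,
   "Na": 0.001,
   "Mg": 0.002,
   "P": 0.103,
   "S": 0.003,
   "Ca": 0.225
  }
 },
 "water": {
  "density_g_cm3": 1.0,
  "mass_fractions": {
   "H": 0.1119,
   "O": 0.8881
  }
 }
}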