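{
 "nuclide": "Lu-177",
 "half_life_days": 6.647,
 "photon_lines_kev_yield": [
  [
   208.37,
   0.1041
  ],
  [
   112.95,
   0.062
  ],
  [
   321.32,
   0.00219
  ],
  [
   249.67,
   0.00212
  ],
  [
   71.64,
   0.00172
  ],
  [
   55.79,
   0.047
  ],
  [
   54.61,
   0.027
  ],
  [
   63.2,
   0.023
  ]
 ],
 "electron_lines_kev_yield": [
  [
   47.6,
   0.098
  ],
  [
   101.9,
   0.027
  ],
  [
   110.7,
   0.0091
  ],
  [
   142.9,
   0.0072
  ],
  [
   197.2,
   0.002
  ],
  [
   206.1,
   0.0007
  ],
  [
   47.0,
   0.005
  ],
  [
   7.0,
   0.12
  ]
 ],
 "beta_branches": [
  [
   498.3,
   0.794,
   72
  ],
  [
   385.3,
   0.091,
   72
  ],
  [
   177.0,
   0.115,
   72
  ]
 ],
 "reference_mean_electron_kev": 147.9,
 "reference_mean_photon_kev": 34.8
}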