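{
 "breakpoints_hu_density": [
  [
   -1000.0,
   0.001205
  ],
  [
   -100.0,
   0.95
  ],
  [
   0.0,
   1.0
  ],
  [
   100.0,
   1.076
  ],
  [
   1600.0,
   1.964
  ],
  [
   3000.0,
   2.8
  ]
 ]
}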