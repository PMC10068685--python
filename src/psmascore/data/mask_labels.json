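{
  "liver": 1,
  "blood_pool": 2,
  "prostate_bed": 3,
  "skeleton": 4,
  "nodal_region": 5
}
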