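{
  "table1_patients.csv": "c893c26eafc872ea3b878bff0adcfbbf96923839f013136c2320863aea146eb8",
  "table2_response.csv": "4833082008a71c06bb7cd974e60e2fc4035f6c23fb92a400d1d8320ecd6ee195"
}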