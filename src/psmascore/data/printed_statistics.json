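{
  "comment": "Published summary statistics of the 30-patient cohort, used as expected values by run_reproduction.",
  "pearson_row": {"nodal": 0.95, "osseous": 0.38, "prostate_bed": -0.06, "composite": 0.61},
  "pearson_tolerance": 0.05,
  "median_decline_pct": {"prostate_bed": 100.0, "nodal": 100.0, "osseous": 100.0},
  "median_psa_decrease_pct": 100.0,
  "median_interval_months": 8.0,
  "n_patients": 30
}
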