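{
  "scenario": {
    "label": "biweekly_nivolumab",
    "regimen": {
      "amount_mg_per_kg": 3.0,
      "interval_days": 14.0,
      "start_day": 30.0,
      "n_doses": 24
    },
    "horizon": 365.0,
    "output_grid_step": 5.0
  },
  "sampling": {"n": 500, "seed": 2019, "gsd": 1.5},
  "output_dir": "psa_out"
}
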