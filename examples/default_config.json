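{
  "model": {},
  "pk": {},
  "scenario": {
    "label": "biweekly_nivolumab",
    "regimen": {
      "amount_mg_per_kg": 3.0,
      "interval_days": 14.0,
      "start_day": 30.0,
      "n_doses": 24
    },
    "horizon": 365.0,
    "output_grid_step": 1.0
  },
  "sampling": {"n": 200, "seed": 1, "gsd": 1.5},
  "n_reps": 50,
  "initial_diameter_mm": 30.0,
  "output_dir": "pd1sim_out",
  "verbosity": "info"
}
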