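{
  "scenario": {
    "label": "neoadjuvant_resection",
    "regimen": {
      "amount_mg_per_kg": 3.0,
      "interval_days": 14.0,
      "start_day": 0.0,
      "n_doses": 2
    },
    "resection_day": 40.0,
    "residual_volume": 1.0,
    "horizon": 365.0
  },
  "output_dir": "resection_out"
}
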