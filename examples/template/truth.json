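{
  "os_family": "weibull",
  "os_params": [
    1.2,
    24.0
  ],
  "progression_family": "weibull",
  "progression_params": [
    1.1,
    10.0
  ],
  "hr_os": 0.7,
  "hr_pfs": 0.5,
  "n_per_arm": 300,
  "censor_time": 36.0,
  "seed": 42
}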