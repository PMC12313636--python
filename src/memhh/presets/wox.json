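{
  "tau": 50.0,
  "alpha": 0.01,
  "beta": 0.5,
  "gamma": 10.0,
  "delta": 4.0,
  "eta": 8.0,
  "lam": 0.001,
  "w_min": 0.1,
  "w_max": 0.99
}
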