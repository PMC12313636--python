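{
  "tau": 11.7,
  "alpha": 0.0271,
  "beta": 0.503,
  "gamma": 11.138,
  "delta": 0.739,
  "eta": 0.739,
  "lam": 0.0155,
  "w_min": 0.117,
  "w_max": 0.99
}
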