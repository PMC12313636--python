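{
  "nbox": {"V_scale": 0.11, "T_scale": 1.26, "I_scale": 1.91},
  "wox": {"V_scale": 0.013, "T_scale": 0.186, "I_scale": 6.317}
}
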