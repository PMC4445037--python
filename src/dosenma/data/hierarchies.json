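{
  "pain": ["VAS_walking", "WOMAC_pain", "VAS_global", "other"],
  "function": ["WOMAC_function", "WOMAC_total", "Lequesne", "other"]
}
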