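{
  "12": ["M", "V", "I"],
  "20": ["F", "L", "Y", "V"],
  "27": ["M", "I", "V", "F"]
}
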