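{
  "12": [
    {"residue": "M", "score": -22.5},
    {"residue": "V", "score": -22.3},
    {"residue": "I", "score": -22.3}
  ],
  "20": [
    {"residue": "F", "score": -20.2},
    {"residue": "L", "score": -20.1},
    {"residue": "Y", "score": -20.1}
  ],
  "27": [
    {"residue": "M", "score": -20.2},
    {"residue": "I", "score": -19.2},
    {"residue": "V", "score": -18.7}
  ]
}
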