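{
  "groups": {
    "g1": ["REFLEX"],
    "g2": ["WA16291"],
    "g34": ["DANCER", "SERENE"]
  },
  "bounds": {
    "g1": [0.1, 0.95],
    "g2": [0.1, 0.95],
    "g34": [0.1, 0.95]
  },
  "order": [["g1", "g2"], ["g34", "g2"]]
}
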