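{
  "speakers": {
    "female": {
      "flat": [300, 250, 200],
      "rising": [[150, 300], [150, 250], [150, 200]],
      "falling": [[300, 220], [300, 170], [300, 120]]
    },
    "male": {
      "flat": [200, 170, 130],
      "rising": [[100, 220], [100, 180], [100, 150]],
      "falling": [[180, 140], [180, 110], [180, 80]]
    }
  },
  "gains_db": {
    "flat": [0, 0],
    "rising": [-10, 10],
    "falling": [10, -10]
  }
}
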