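{
  "version": "abgraft-vernier-1.0",
  "scheme": "kabat",
  "provenance": "Vernier-zone framework positions of Foote & Winter (1992) J Mol Biol 224:487-499, Kabat numbering.",
  "positions": {
    "heavy": [2, 27, 28, 29, 30, 47, 48, 49, 67, 69, 71, 73, 78, 93, 94, 103],
    "kappa": [2, 4, 35, 36, 46, 47, 48, 49, 64, 66, 68, 69, 71, 98],
    "lambda": [2, 4, 35, 36, 46, 47, 48, 49, 64, 66, 68, 69, 71, 98]
  }
}
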