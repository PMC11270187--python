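{
  "version": "abgraft-vdw-1.0",
  "provenance": "Van der Waals radii of Bondi (1964) J Phys Chem 68:441, with the Rowland & Taylor (1996) H radius.",
  "radii": {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "FE": 1.60,
    "MN": 1.60,
    "CU": 1.40,
    "NI": 1.63
  }
}
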