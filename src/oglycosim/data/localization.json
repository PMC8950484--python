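{
  "comment": "Binary glycosyltransferase localization across the four Golgi compartments, assigned by pathway role: core 1/3 synthesis in cis, core 2/4 branching peaking in medial, elongation and capping in trans/TGN, fucosyltransferases in medial+trans, CHST4 everywhere except cis.",
  "compartments": ["cis", "medial", "trans", "tgn"],
  "localization": {
    "C1GALT1": [1, 0, 0, 0],
    "B3GNT6": [1, 0, 0, 0],
    "GCNT1": [0, 1, 0, 0],
    "GCNT3": [0, 1, 0, 0],
    "B3GNT": [0, 0, 1, 1],
    "B3GNT3": [0, 0, 1, 1],
    "B4GALT": [0, 0, 1, 1],
    "B3GALT5": [0, 0, 1, 1],
    "B4GALNT3": [0, 0, 1, 1],
    "A4GNT": [0, 0, 1, 1],
    "A3GALT": [0, 0, 1, 1],
    "A4GALT": [0, 0, 1, 1],
    "FUT2": [0, 1, 1, 0],
    "FUT3": [0, 1, 1, 0],
    "FUT4": [0, 1, 1, 0],
    "FUT7": [0, 1, 1, 0],
    "ST3GAL": [0, 0, 1, 1],
    "ST6GAL1": [0, 0, 1, 1],
    "ST6GALNAC": [0, 0, 1, 1],
    "CHST4": [0, 1, 1, 1]
  }
}
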