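{
  "comment": "Nucleotide-sugar / PAPS donor concentrations (uM) per Golgi compartment, clamped during simulation. Donors are supplied only in the compartments where they donate, following the enzyme distribution.",
  "compartments": ["cis", "medial", "trans", "tgn"],
  "donors": {
    "CMP_NeuAc": [0, 0, 3000, 3000],
    "CMP_NeuGc": [0, 0, 3000, 3000],
    "GDP_Fuc": [0, 5000, 5000, 0],
    "UDP_GlcNAc": [9143, 9143, 9143, 0],
    "UDP_Gal": [3810, 0, 3810, 3810],
    "UDP_GalNAc": [0, 0, 3000, 0],
    "PAP_S": [0, 920, 920, 920]
  }
}
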