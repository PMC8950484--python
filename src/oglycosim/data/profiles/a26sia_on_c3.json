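{
 "name": "a2,6sialic acid on C3",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "NeuAcα2-6Galβ1-4GlcNAcβ1-3GalNAcol",
   "value": 50.0,
   "charge": 1
  },
  {
   "structure": "Galβ1-4GlcNAcβ1-3GalNAcol",
   "value": 31.25,
   "charge": 0
  },
  {
   "structure": "GlcNAcβ1-3GalNAcol",
   "value": 18.75,
   "charge": 0
  }
 ]
}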