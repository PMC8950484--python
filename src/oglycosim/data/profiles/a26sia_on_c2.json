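{
 "name": "a2,6sialic acid on C2",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "NeuAcα2-6Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcol",
   "value": 44.44444444444444,
   "charge": 1
  },
  {
   "structure": "Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcol",
   "value": 27.77777777777778,
   "charge": 0
  },
  {
   "structure": "Galβ1-3(GlcNAcβ1-6)GalNAcol",
   "value": 16.666666666666668,
   "charge": 0
  },
  {
   "structure": "Galβ1-3GalNAcol",
   "value": 11.11111111111111,
   "charge": 0
  }
 ]
}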