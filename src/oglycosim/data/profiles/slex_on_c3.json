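{
 "name": "Slex on C3",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "Galβ1-4GlcNAcβ1-3GalNAcol",
   "value": 50.0,
   "charge": 0
  },
  {
   "structure": "NeuAcα2-3Galβ1-4GlcNAcβ1-3GalNAcol",
   "value": 20.0,
   "charge": 1
  },
  {
   "structure": "NeuAcα2-3Galβ1-4(Fucα1-3)GlcNAcβ1-3GalNAcol",
   "value": 15.0,
   "charge": 1
  },
  {
   "structure": "GlcNAcβ1-3GalNAcol",
   "value": 15.0,
   "charge": 0
  }
 ]
}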