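{
 "name": "ExC1",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "NeuAcα2-3Galβ1-4(6S)GlcNAcβ1-3Galβ1-3GalNAcol",
   "value": 40.0,
   "charge": 2
  },
  {
   "structure": "NeuAcα2-3Galβ1-4GlcNAcβ1-3Galβ1-3GalNAcol",
   "value": 25.0,
   "charge": 1
  },
  {
   "structure": "Galβ1-4(6S)GlcNAcβ1-3Galβ1-3GalNAcol",
   "value": 15.0,
   "charge": 1
  },
  {
   "structure": "Galβ1-4GlcNAcβ1-3Galβ1-3GalNAcol",
   "value": 10.0,
   "charge": 0
  },
  {
   "structure": "GlcNAcβ1-3Galβ1-3GalNAcol",
   "value": 6.0,
   "charge": 0
  },
  {
   "structure": "Galβ1-3GalNAcol",
   "value": 4.0,
   "charge": 0
  }
 ]
}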