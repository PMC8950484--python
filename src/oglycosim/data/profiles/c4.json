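{
 "name": "C4",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "Galβ1-4(6S)GlcNAcβ1-3(Galβ1-4(6S)GlcNAcβ1-6)GalNAcol",
   "value": 40.0,
   "charge": 2
  },
  {
   "structure": "Galβ1-4(6S)GlcNAcβ1-3(Galβ1-4GlcNAcβ1-6)GalNAcol",
   "value": 25.0,
   "charge": 1
  },
  {
   "structure": "Galβ1-4GlcNAcβ1-3(Galβ1-4(6S)GlcNAcβ1-6)GalNAcol",
   "value": 15.0,
   "charge": 1
  },
  {
   "structure": "Galβ1-4GlcNAcβ1-3(Galβ1-4GlcNAcβ1-6)GalNAcol",
   "value": 10.0,
   "charge": 0
  },
  {
   "structure": "6SGlcNAcβ1-3(Galβ1-4(6S)GlcNAcβ1-6)GalNAcol",
   "value": 6.0,
   "charge": 2
  },
  {
   "structure": "6SGlcNAcβ1-3(Galβ1-4GlcNAcβ1-6)GalNAcol",
   "value": 4.0,
   "charge": 1
  }
 ]
}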