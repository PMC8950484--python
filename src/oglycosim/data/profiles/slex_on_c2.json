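{
 "name": "Slex on C2",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "NeuAcα2-3Galβ1-4(Fucα1-3)GlcNAcβ1-6(Galβ1-3)GalNAcol",
   "value": 41.666666666666664,
   "charge": 1
  },
  {
   "structure": "NeuAcα2-3Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcol",
   "value": 26.041666666666668,
   "charge": 1
  },
  {
   "structure": "Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcol",
   "value": 15.625,
   "charge": 0
  },
  {
   "structure": "Galβ1-3(GlcNAcβ1-6)GalNAcol",
   "value": 10.416666666666666,
   "charge": 0
  },
  {
   "structure": "Galβ1-3GalNAcol",
   "value": 6.25,
   "charge": 0
  }
 ]
}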