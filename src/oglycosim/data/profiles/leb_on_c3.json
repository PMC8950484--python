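{
 "name": "Leb on C3",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "Fucα1-2Galβ1-3(Fucα1-4)GlcNAcβ1-3GalNAcol",
   "value": 40.0,
   "charge": 0
  },
  {
   "structure": "Fucα1-2Galβ1-4(Fucα1-3)GlcNAcβ1-3GalNAcol",
   "value": 25.0,
   "charge": 0
  },
  {
   "structure": "Fucα1-2Galβ1-3GlcNAcβ1-3GalNAcol",
   "value": 15.0,
   "charge": 0
  },
  {
   "structure": "Fucα1-2Galβ1-4GlcNAcβ1-3GalNAcol",
   "value": 10.0,
   "charge": 0
  },
  {
   "structure": "Galβ1-3(Fucα1-4)GlcNAcβ1-3GalNAcol",
   "value": 6.0,
   "charge": 0
  },
  {
   "structure": "Galβ1-4(Fucα1-3)GlcNAcβ1-3GalNAcol",
   "value": 4.0,
   "charge": 0
  }
 ]
}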