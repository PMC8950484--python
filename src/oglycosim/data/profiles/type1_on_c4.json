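{
 "name": "Terminal type 1 on C4",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "Galβ1-3GlcNAcβ1-3(Galβ1-3GlcNAcβ1-6)GalNAcol",
   "value": 40.0,
   "charge": 0
  },
  {
   "structure": "Galβ1-3GlcNAcβ1-3(GlcNAcβ1-6)GalNAcol",
   "value": 25.0,
   "charge": 0
  },
  {
   "structure": "Galβ1-3GlcNAcβ1-6(GlcNAcβ1-3)GalNAcol",
   "value": 15.0,
   "charge": 0
  },
  {
   "structure": "Galβ1-3GlcNAcβ1-3GalNAcol",
   "value": 10.0,
   "charge": 0
  },
  {
   "structure": "GlcNAcβ1-3(GlcNAcβ1-6)GalNAcol",
   "value": 6.0,
   "charge": 0
  },
  {
   "structure": "GlcNAcβ1-3GalNAcol",
   "value": 4.0,
   "charge": 0
  }
 ]
}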