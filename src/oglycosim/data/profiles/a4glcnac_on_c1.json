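{
 "name": "A4GlcNAc on C1",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "GlcNAcα1-4Galβ1-3GalNAcol",
   "value": 60.0,
   "charge": 0
  },
  {
   "structure": "Galβ1-3GalNAcol",
   "value": 40.0,
   "charge": 0
  }
 ]
}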