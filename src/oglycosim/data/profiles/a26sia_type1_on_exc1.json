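{
 "name": "a2,6sialic acid with type 1 on exC1",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "NeuAcα2-6Galβ1-4GlcNAcβ1-3Galβ1-3GalNAcol",
   "value": 41.666666666666664,
   "charge": 1
  },
  {
   "structure": "Galβ1-3GlcNAcβ1-3Galβ1-3GalNAcol",
   "value": 26.041666666666668,
   "charge": 0
  },
  {
   "structure": "Galβ1-4GlcNAcβ1-3Galβ1-3GalNAcol",
   "value": 15.625,
   "charge": 0
  },
  {
   "structure": "GlcNAcβ1-3Galβ1-3GalNAcol",
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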