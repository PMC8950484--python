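{
 "name": "CHO/CHO-WT",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "Galβ1-3(NeuAcα2-6)GalNAcol",
   "value": 45.0,
   "charge": 1
  },
  {
   "structure": "NeuAcα2-3Galβ1-3GalNAcol",
   "value": 20.0,
   "charge": 1
  },
  {
   "structure": "NeuAcα2-3Galβ1-3(NeuAcα2-6)GalNAcol",
   "value": 35.0,
   "charge": 2
  }
 ]
}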