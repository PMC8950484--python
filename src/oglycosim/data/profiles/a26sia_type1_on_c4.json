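{
 "name": "a2,6sialic acid with type 1 on C4",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "NeuAcα2-6Galβ1-4GlcNAcβ1-3(NeuAcα2-6Galβ1-4GlcNAcβ1-6)GalNAcol",
   "value": 40.0,
   "charge": 2
  },
  {
   "structure": "NeuAcα2-6Galβ1-4GlcNAcβ1-3(Galβ1-3GlcNAcβ1-6)GalNAcol",
   "value": 25.0,
   "charge": 1
  },
  {
   "structure": "NeuAcα2-6Galβ1-4GlcNAcβ1-3(Galβ1-4GlcNAcβ1-6)GalNAcol",
   "value": 15.0,
   "charge": 1
  },
  {
   "structure": "NeuAcα2-6Galβ1-4GlcNAcβ1-6(Galβ1-3GlcNAcβ1-3)GalNAcol",
   "value": 10.0,
   "charge": 1
  },
  {
   "structure": "NeuAcα2-6Galβ1-4GlcNAcβ1-6(Galβ1-4GlcNAcβ1-3)GalNAcol",
   "value": 6.0,
   "charge": 1
  },
  {
   "structure": "Galβ1-3GlcNAcβ1-3(Galβ1-3GlcNAcβ1-6)GalNAcol",
   "value": 4.0,
   "charge": 0
  }
 ]
}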