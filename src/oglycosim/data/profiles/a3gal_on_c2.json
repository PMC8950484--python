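{
 "name": "a1,3Gal on C2",
 "kind": "adjusted",
 "synthetic": true,
 "entries": [
  {
   "structure": "Galα1-3Galβ1-4GlcNAcβ1-3Galα1-3Galβ1-3(GlcNAcβ1-3Galα1-3Galβ1-4GlcNAcβ1-6)GalNAcol",
   "value": 40.0,
   "charge": 0
  },
  {
   "structure": "Galα1-3Galβ1-4GlcNAcβ1-3Galα1-3Galβ1-4GlcNAcβ1-3Galα1-3Galβ1-3(GlcNAcβ1-6)GalNAcol",
   "value": 25.0,
   "charge": 0
  },
  {
   "structure": "Galα1-3Galβ1-4GlcNAcβ1-3Galα1-3Galβ1-4GlcNAcβ1-6(GlcNAcβ1-3Galα1-3Galβ1-3)GalNAcol",
   "value": 15.0,
   "charge": 0
  },
  {
   "structure": "Galβ1-4GlcNAcβ1-3Galα1-3Galβ1-4GlcNAcβ1-3Galα1-3Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAcol",
   "value": 10.0,
   "charge": 0
  },
  {
   "structure": "Galβ1-4GlcNAcβ1-3Galα1-3Galβ1-4GlcNAcβ1-3Galα1-3Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcol",
   "value": 6.0,
   "charge": 0
  },
  {
   "structure": "Galβ1-4GlcNAcβ1-3Galα1-3Galβ1-4GlcNAcβ1-6(Galβ1-4GlcNAcβ1-3Galα1-3Galβ1-3)GalNAcol",
   "value": 4.0,
   "charge": 0
  }
 ]
}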