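{
 "description": "Published post-intervention posterior marginals for every network node. The source table prints two rows both labelled for the talocrural joint; the second pair (0.577/0.423) is read as the subtalar joint R2. The R1 pair sums to 0.996 as printed; whether loaders renormalise is a config switch (default: keep as printed).",
 "marginals": {
  "P1": [0.3, 0.5, 0.2],
  "B1": [0.445, 0.43, 0.125],
  "B2": [0.355, 0.455, 0.19],
  "B3": [0.315, 0.485, 0.2],
  "B4": [0.495, 0.434, 0.071],
  "R1": [0.584, 0.412],
  "R2": [0.577, 0.423],
  "G1": [0.629, 0.371],
  "G2": [0.676, 0.324],
  "G3": [0.676, 0.324],
  "G4": [0.658, 0.342]
 }
}
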