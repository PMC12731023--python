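{
 "description": "Published baseline (pre-intervention) node proportions. The source lists a single state-probability per node, not full distributions; loaders spread the remaining mass equally over the unlisted states and flag those entries 'imputed'. Two printed rows are internally inconsistent with the binary codings (R1 'state 2', G2 'state 2') and are kept verbatim with a note.",
 "entries": [
  {"node": "P1", "state": 0, "probability": 0.22},
  {"node": "B1", "state": 1, "probability": 0.38},
  {"node": "B2", "state": 2, "probability": 0.4},
  {"node": "B3", "state": 0, "probability": 0.28},
  {"node": "B4", "state": 1, "probability": 0.52},
  {"node": "R1", "state": 2, "probability": 0.2,
   "note": "printed state 2 on a binary node; unusable as-is"},
  {"node": "R2", "state": 0, "probability": 0.18},
  {"node": "G1", "state": 1, "probability": 0.53},
  {"node": "G2", "state": 2, "probability": 0.29,
   "note": "printed state 2 on a binary node; unusable as-is"},
  {"node": "G3", "state": 0, "probability": 0.19},
  {"node": "G4", "state": 1, "probability": 0.56}
 ]
}
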