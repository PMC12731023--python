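{
 "description": "Default clinical network for the ankle-rehabilitation decision model. Goal-node tables (G1-G4) are the published reference conditional probabilities; the G4 column in the source table printed duplicated achieved/not-achieved values and is loaded as achieved-probability p with complement 1-p (flagged 'corrected'). Repair- and functional-node tables are assumed defaults chosen so that prior marginals roughly reproduce the published baseline proportions (repair achieved ~0.30, functional-state marginals within ~0.02); they are generator inputs, not claims.",
 "nodes": [
  {"id": "P1", "states": [0, 1, 2], "parents": []},
  {"id": "R1", "states": [0, 1], "parents": ["P1"]},
  {"id": "R2", "states": [0, 1], "parents": ["P1"]},
  {"id": "B1", "states": [0, 1, 2], "parents": ["R1"]},
  {"id": "B2", "states": [0, 1, 2], "parents": ["R2"]},
  {"id": "B3", "states": [0, 1, 2], "parents": ["R2"]},
  {"id": "B4", "states": [0, 1, 2], "parents": ["R1"]},
  {"id": "G1", "states": [0, 1], "parents": ["R1", "R2"]},
  {"id": "G2", "states": [0, 1], "parents": ["R1", "R2"]},
  {"id": "G3", "states": [0, 1], "parents": ["R1", "R2"]},
  {"id": "G4", "states": [0, 1], "parents": ["R1", "R2"]}
 ],
 "cpts": {
  "P1": {"table": [0.22, 0.39, 0.39],
         "provenance": "grade-I proportion published; remaining mass imputed equally"},
  "R1": {"table": [[0.85, 0.15], [0.25, 0.75], [0.05, 0.95]],
         "provenance": "assumed default"},
  "R2": {"table": [[0.85, 0.15], [0.25, 0.75], [0.05, 0.95]],
         "provenance": "assumed default"},
  "B1": {"table": [[0.85, 0.13, 0.02], [0.08, 0.50, 0.42]],
         "provenance": "assumed default"},
  "B2": {"table": [[0.80, 0.17, 0.03], [0.05, 0.38, 0.57]],
         "provenance": "assumed default"},
  "B3": {"table": [[0.75, 0.20, 0.05], [0.07, 0.55, 0.38]],
         "provenance": "assumed default"},
  "B4": {"table": [[0.70, 0.27, 0.03], [0.13, 0.63, 0.24]],
         "provenance": "assumed default"},
  "G1": {"table": [[[0.85, 0.15], [0.60, 0.40]], [[0.60, 0.40], [0.30, 0.70]]],
         "provenance": "reference"},
  "G2": {"table": [[[0.92, 0.08], [0.70, 0.30]], [[0.60, 0.40], [0.30, 0.70]]],
         "provenance": "reference"},
  "G3": {"table": [[[0.90, 0.10], [0.65, 0.35]], [[0.75, 0.25], [0.25, 0.75]]],
         "provenance": "reference"},
  "G4": {"table": [[[0.95, 0.05], [0.85, 0.15]], [[0.50, 0.50], [0.12, 0.88]]],
         "provenance": "reference; corrected from duplicated printed columns"}
 }
}
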