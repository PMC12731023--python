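{
 "description": "Factor scores for node states (hierarchical classification of intervention weight, 1-5). Goal nodes G1-G4 carry a score only for the achieved state (0); unachieved states are deliberately unscored.",
 "goal_nodes": ["G1", "G2", "G3", "G4"],
 "scores": [
  {"node": "P1", "state": 0, "label": "Level I", "score": 2},
  {"node": "P1", "state": 1, "label": "Level II", "score": 3},
  {"node": "P1", "state": 2, "label": "Level III", "score": 5},
  {"node": "B1", "state": 0, "label": "normal", "score": 1},
  {"node": "B1", "state": 1, "label": "mildly restricted", "score": 3},
  {"node": "B1", "state": 2, "label": "severely restricted", "score": 5},
  {"node": "B2", "state": 0, "label": "normal", "score": 1},
  {"node": "B2", "state": 1, "label": "mildly restricted", "score": 3},
  {"node": "B2", "state": 2, "label": "severely restricted", "score": 5},
  {"node": "B3", "state": 0, "label": "normal", "score": 1},
  {"node": "B3", "state": 1, "label": "mildly restricted", "score": 2},
  {"node": "B3", "state": 2, "label": "severely restricted", "score": 4},
  {"node": "B4", "state": 0, "label": "normal", "score": 1},
  {"node": "B4", "state": 1, "label": "mildly restricted", "score": 2},
  {"node": "B4", "state": 2, "label": "severely restricted", "score": 3},
  {"node": "R1", "state": 0, "label": "recovered", "score": 2},
  {"node": "R1", "state": 1, "label": "impaired", "score": 5},
  {"node": "R2", "state": 0, "label": "recovered", "score": 2},
  {"node": "R2", "state": 1, "label": "impaired", "score": 4},
  {"node": "G1", "state": 0, "label": "achieved", "score": 3},
  {"node": "G2", "state": 0, "label": "achieved", "score": 3},
  {"node": "G3", "state": 0, "label": "achieved", "score": 4},
  {"node": "G4", "state": 0, "label": "achieved", "score": 5}
 ]
}
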