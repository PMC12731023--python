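{
 "description": "Published per-feature entropy/information-gain table for the four clinical features of the ankle cohort (pain level A1, swelling diameter A2, joint stability A3, functional limitation A4). The printed table duplicates two feature labels; ids follow the feature-set definition in the study prose. The printed IG values are consistent with an implied dataset entropy of 1.492 bits (IG_j + H(D|A_j) = 1.492 for all four features), not with the separately printed worked-example value of 1.58 bits; only the internal-consistency property is asserted by tests.",
 "implied_h_d": 1.492,
 "features": [
  {"id": "A1", "name": "pain level",
   "value_entropies": {"mild": 1.385, "moderate": 1.512, "severe": 1.436},
   "conditional_entropy": 1.428, "information_gain": 0.064},
  {"id": "A2", "name": "swelling diameter",
   "value_entropies": {"limited": 1.402, "medium": 1.425, "wide": 1.328},
   "conditional_entropy": 1.395, "information_gain": 0.097},
  {"id": "A3", "name": "joint stability",
   "value_entropies": {"stable": 1.086, "basic": 1.418, "unstable": 0.935},
   "conditional_entropy": 1.152, "information_gain": 0.34},
  {"id": "A4", "name": "functional limitation",
   "value_entropies": {"mild": 0.768, "moderate": 1.285, "severe": 0.683},
   "conditional_entropy": 0.901, "information_gain": 0.591}
 ]
}
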