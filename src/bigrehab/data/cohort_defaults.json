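{
 "description": "Default generator settings for the synthetic cohort: grade-conditioned ordinal-feature tables (rows: Level I/II/III, columns: low/mid/high), state-conditioned signal-noise parameters, and the per-session Markov improvement kernel. The published study names the clinical signals but no distributions; these defaults emulate its stated feature structure: pain and swelling only weakly correlated with grade, stability moderately informative, and functional limitation (derived from the node chain) the most discriminative feature.",
 "grade_probs": [0.22, 0.39, 0.39],
 "feature_tables": {
  "A1": [[0.40, 0.35, 0.25], [0.33, 0.34, 0.33], [0.28, 0.35, 0.37]],
  "A2": [[0.42, 0.33, 0.25], [0.33, 0.34, 0.33], [0.25, 0.33, 0.42]],
  "A3": [[0.55, 0.33, 0.12], [0.30, 0.45, 0.25], [0.12, 0.35, 0.53]]
 },
 "levels": ["low", "mid", "high"],
 "grades": ["I", "II", "III"],
 "noise": {
  "n_emg_channels": 3,
  "emg_base_mean": 0.2,
  "emg_severity_shift": 0.15,
  "emg_channel_offset": 0.05,
  "emg_sd": 0.05,
  "traj_base_mean_mm": 1.0,
  "traj_severity_shift_mm": 1.5,
  "traj_sd_mm": 0.5
 },
 "improvement": {"R": 0.133, "B": 0.133, "G": 0.133},
 "n_sessions": 6,
 "discordance_rate": 0.1
}
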