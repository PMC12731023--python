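{
 "description": "Illustrative symmetric 3-branch geometry for the 3-PUU-R mechanism (metres): three vertical prismatic axes on a 0.12 m base circle at 120 deg spacing, platform attachments on a 0.08 m circle, 0.20 m rods, 0-0.30 m strokes, pedal pivot 0.05 m above the platform centre. The published design prints no dimensions; these are plausible values scaled to the device's 20-30 cm foot-length range and are for analysis examples only.",
 "base_points": [
  [0.0, 0.12, 0.0],
  [-0.10392304845413263, -0.06, 0.0],
  [0.10392304845413263, -0.06, 0.0]
 ],
 "platform_points": [
  [0.0, 0.08, 0.0],
  [-0.06928203230275509, -0.04, 0.0],
  [0.06928203230275509, -0.04, 0.0]
 ],
 "directions": [
  [0.0, 0.0, 1.0],
  [0.0, 0.0, 1.0],
  [0.0, 0.0, 1.0]
 ],
 "rod_lengths": [0.2, 0.2, 0.2],
 "stroke_limits": [[0.0, 0.3], [0.0, 0.3], [0.0, 0.3]],
 "pedal_offset": [0.0, 0.0, 0.05]
}
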