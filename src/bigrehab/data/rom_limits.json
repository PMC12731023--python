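{
 "description": "Ankle range-of-motion limits in degrees (all motions measured from neutral, so limits are maxima and angles are non-negative). Two physiological presets are shipped because the published sources disagree on external rotation: the tabulated limits give 10 deg while the device-design prose gives 50 deg. The gait preset bounds every motion by its physiological limit.",
 "presets": {
  "physiological": {
   "plantarflexion": 50, "dorsiflexion": 30,
   "inversion": 25, "eversion": 15,
   "internal_rotation": 20, "external_rotation": 10
  },
  "physiological_extended": {
   "plantarflexion": 50, "dorsiflexion": 30,
   "inversion": 25, "eversion": 15,
   "internal_rotation": 20, "external_rotation": 50
  },
  "gait": {
   "plantarflexion": 40, "dorsiflexion": 10,
   "inversion": 10, "eversion": 5,
   "internal_rotation": 5, "external_rotation": 5
  }
 }
}
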