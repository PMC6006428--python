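{
 "seed": 42,
 "phantom": {
  "architecture": "crnpc",
  "voxel_size_nm": 3.0,
  "box_nm": 132.0,
  "resolution_nm": 6.0,
  "n_particles": 6,
  "snr": 1.0,
  "tilt_min": -60.0,
  "tilt_max": 60.0
 },
 "averaging": {"enabled": true, "n_iter": 2, "symmetry_order": 8, "angular_step_deg": 10.0},
 "fitting": {
  "enabled": true,
  "hierarchy": ["Y-complex", "IR-protomer"],
  "angular_step_deg": 24.0,
  "alpha": 0.05
 },
 "analysis": {"enabled": true},
 "coexpr": {"enabled": false}
}
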