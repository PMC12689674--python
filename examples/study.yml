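# Full default factorial study: 3 designs x 3 heights x 2 instruments x 5
# replicates. Every key below is optional; unknown keys are rejected.
seed: 1
output_dir: out

design:
  designs: [SS, FS, AS]
  heights: [1, 2, 3]
  instruments: [saw, piezo]
  replicates: 5
  segment_lengths: [30, 32, 30]   # planned vestibular lengths, mm
  wedge_angles: [45, 45]          # closing wedges at the two joints, deg

fibula:
  shaft_length: 140.0
  cross_section_width: 14.0

guide:
  slot_width: 1.0
  kerf_saw: 0.3
  kerf_piezo: 0.45

# per-cell overrides of the built-in perturbation conditions
# perturbation:
#   - {design: SS, height: 1, instrument: saw, tilt_sd: 2.5,
#      truncate_at_groove_bound: true}

icp:
  subsample: 2000
  max_iterations: 100
  tol: 1.0e-6

pipeline:
  with_reconstruction: true
  detect_faces: false
  export_heatmaps: false
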