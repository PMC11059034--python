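rng_seed: 0
output_dir: runs/demo
phantom:
  n_patients: 2
  phase_start_pct: 20.0
  phase_end_pct: 80.0
  phase_step_pct: 3.0
  slices_per_phase: 1
  H: 64
  W: 64
geometry:
  n_views: 180
  n_detectors: 4
  detector_spacing_mm: 3.2
  source_to_iso_mm: 540.0
  source_to_detector_mm: 950.0
  rotation_time_ms: 350.0
  fov_mm: 220.0
recon:
  filter_name: ram-lak
  angular_range_deg: 120.0
  start_angle_deg: 120.0
  sart_iterations: 10
  sart_relaxation: 1.0
  tv_iterations_per_sart: 20
  tv_step: 0.2
model:
  preset: uswin1
  predict_residual: false
train:
  batch_size: 1
  epochs: 100
  learning_rate: 1.0e-05
  max_steps: 0
  k_folds: 10
  checkpoint_every: 0
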