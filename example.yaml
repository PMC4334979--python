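out_dir: scratch/example_run
rng_seed: 20150205
simulate:
  n_group_a: 12
  n_group_b: 12
  grid_dims: [20, 20, 14]
  n_volumes: 160
  mask_radius_mm: 27.0
  planted_effects:
    - center_mm: [-9.0, 9.0, 3.0]
      radius_mm: 9.0
      local_coupling_a: 0.6
      local_coupling_b: 0.0
      remote_center_mm: [12.0, -12.0, -3.0]
      remote_radius_mm: 7.5
      connectivity_slope: 0.5
      score_link: 250.0
cluster:
  p_voxel: 0.01
  alpha: 0.05
  n_iterations: 1000
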