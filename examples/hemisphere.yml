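# One pass over a 1 m hemisphere "canopy" centred in plot (0, 0).
scene:
  ground_z: 0.0
  shapes:
    - kind: hemisphere
      center: [1.5, 0.0]
      radius: 1.0

pass:
  path: [0.0, 3.05, 0.0]   # x_start, x_end, y (m); travels along +x
  speed: 0.5               # m/s
  f_gps: 5.0               # Hz
  f_lidar: 50.0            # Hz
  aperture_deg: 190.0
  resolution_deg: 0.333333333333333333
  sensor_height: 2.4       # m above ground
  range_noise_sd: 0.005    # m (1 sigma)

sensor:
  f_gps: 5.0
  f_lidar: 50.0
  sensor_height: 2.4
  d_offset: [0.0, 0.0, 0.0]
  enclosure_range_bounds: [0.5, 3.0]   # accepted raw ranges (m)

layout:
  n_rows: 16
  n_cols: 8
  plot_width: 3.05
  inter_row: 1.52
  inter_col: 1.83
  origin: [0.0, 0.0]

segmentation:
  ransac_dist_threshold: 0.03
  ransac_n_iter: 1000
  cluster_tolerance: 0.05
  min_cluster_size: 30
  margin_frac: 0.1

traits:
  z_min: 0.05
  pca_method: alpha_shape
  grid_cell: 0.02

plots:
  - [0, 0]

seed: 1
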