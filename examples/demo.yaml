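# Demo: synthetic X-junction (two neural processes crossing 300 nm apart in
# z), imaged in astigmatic 3D mode, then localized, color coded, crosstalk
# corrected, rendered, and summarized as a resolution report.
#
#   smlm run --config examples/demo.yaml --out scratch/demo
seed: 7
stages: [simulate, localize, drift, colors, crosstalk, render, resolution]
simulate:
  structure:
    kind: x_junction
    tube_radius_nm: 75.0
    axis_nm: [[1300.0, 1600.0, 0.0], [3900.0, 1600.0, 0.0]]
    label_density: 150.0
    z_separation_nm: 300.0
  schedule:
    channels: [ch405]
    n_activation: 1
    n_imaging: 3
  blink:
    mean_localizations_per_label: 4.0
    nonspecific_rate: 2.0e-5
    photons_mean: 5000.0
  camera:
    pixel_size_nm: 160.0
    background: 10.0
    offset: 100.0
    read_noise: 2.0
  n_frames: 16000
  shape_px: [26, 33]
  drift_total_nm: [60.0, -40.0]
localize:
  mode: 3d
  threshold_k: 5.0
drift:
  bin_size: 4000
  render_pixel_nm: 25.0
colors: {}
crosstalk: {}
render:
  pitch_nm: 25.0
  mode: 2d
resolution:
  d: 2
  n_locs_per_label: 4.0
  precision_xy_nm: 18.0
  regions:
    - {x_nm: [1400.0, 2400.0], y_nm: [1200.0, 2000.0], measure_um: 0.4712}
    - {x_nm: [2800.0, 3800.0], y_nm: [1200.0, 2000.0], measure_um: 0.4712}
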