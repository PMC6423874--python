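# The artificial flat-mesh experiment: two 625-point square meshes
# (x, y in [-125, 125] mm) at z = 1100 mm (source) and z = 1200 mm (target),
# perturbed by ToF localization noise, registered with the annealed
# stiffness schedule (alpha 100, halved every 20 iterations, 100 iterations).
registration:
  variant: anisotropic
  alpha_start: 100.0
  alpha_decay: 0.5
  alpha_period: 20
  beta: 1.0
  max_iterations: 100
  connectivity: 4
noise:
  sigma_x: 0.02
  sigma_y: 0.02
  sigma_z: 10.0
  camera_origin: [0.0, 0.0, 0.0]
fixture:
  kind: flat_pair
  rows: 25
  cols: 25
  x_bounds: [-125.0, 125.0]
  y_bounds: [-125.0, 125.0]
  source_z: 1100.0
  target_z: 1200.0
  seed: 0
output_dir: runs/flat_noisy
log_level: INFO
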