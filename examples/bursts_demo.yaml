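# Demo: kiss-and-run burst experiment on a small field.
# Run:  vactraffic all --config examples/bursts_demo.yaml --seed 5 --out out/
experiment: bursts
seed: 5
n_pve: 2
photobleach_efficiency: 1.0
optics:
  n_z: 14
  n_y: 64
  n_x: 64
  voxel_xy: 80.0
  voxel_z: 0.30
  frame_interval: 5.0
  n_frames: 60
kinetics:
  quiescent_prob: 0.0
  burst_rate: 0.00333333333
  burst_fraction_mean: 0.375
  pve_leak_rate: 0.0005
analysis:
  burst_interval: 10.0
  burst_threshold: 0.15
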