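# Demo: full characterization pipeline on synthetic data.
#   neurochar run -c examples/demo_config.yaml -o demo_out
seed: 7
cells:
  n: 120
  trace_dt_ms: 0.05
complexity:
  runtime_step_s: 1.0e-5   # measured mean wall-clock seconds per step
  target_rate_hz: 10.0
clustering:
  variance_threshold: 0.95
  min_cluster_size: 10
channels:
  families: [Kv, Nav]
  n_per_family: 8
  grid_points: 128
  variance_threshold: 0.99
ncd:
  n_boot: 2000
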