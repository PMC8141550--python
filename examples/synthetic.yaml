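# Default desk-scale synthetic study: 51 hybrid replicas of 150 ns at 150 mM,
# frames every 0.05 ns. All omitted keys take documented defaults.
seed: 1
output_dir: ionbind_out
synthetic:
  mode: hybrid
  n_replicas: 51
  duration_ns: 150.0
  dt_frame_ns: 0.05
kinetics:
  grid_dt_ns: 0.1
  n_boot: 200
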