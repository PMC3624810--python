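# gapguide run --config docs/experiment.example.yaml
n_sets: 20
seed: 0
restarts: 3
conditions: [own, canonical, wrong]
trimming: true
out_dir: experiment_out
simulation:
  n_taxa: 16
  shape: symmetric
  root_length: 300
  indel_rate: 0.02
  branch_length: 0.25
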