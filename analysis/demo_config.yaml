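# Demo pipeline config: two-arm HU study on a mid-sized synthetic reference.
# Run:  vdjrep run --config analysis/demo_config.yaml --seed 1 --out results/demo

reference:
  toy: {n_v_per_zone: [8, 4, 3], n_d: 4, n_j: 3, seed: 5}

simulate:
  n_per_library: 2000
  libraries: {control: 4, HU: 4}
  conditions: {control: control, HU: HU}

pairs: [[control, HU]]

features:
  length_set: [11, 12, 13, 14]
  cdr3_cap: 30
  trim_cap: 10

stats:
  alpha: 0.05
  metric: shannon

seed: 1
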