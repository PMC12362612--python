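# Example run configuration for the CLI, e.g.:
#   fatebias fate --config examples/config_controlled_toggle.yaml --out-dir out
model: controlled_toggle
params:
  beta: 1.0
  gamma: 100.0
controller:
  sense_species: Y1          # negative feedback: sense the actuated target
  input_species: U1
  actuation: additive_activation
  target_species: Y1
simulation:
  n: 400
  t_end: 200.0
  omega: 50
  seed: 11
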