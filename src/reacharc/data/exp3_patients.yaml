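# Individual-level visible/invisible-hand runs for two synthetic reachers
# emulating recent cerebellar stroke (slow, variable, vision-dependent).
experiment: visible_invisible
population: null
reachers:
  patient1: patient1
  patient2: patient2
protocol:
  n_trials_per_condition: 100
  n_practice: 10
analysis:
  design: individual
  n_permutations: 10000
seed: 11
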