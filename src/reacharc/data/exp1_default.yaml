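# Default visible/invisible-hand cohort run: 20 healthy synthetic reachers,
# 100 trials per condition, population calibrated to typical published group
# values for this paradigm (visible ~2.2 deg, invisible ~3.8 deg mean error).
experiment: visible_invisible
n_participants: 20
population: exp1
protocol:
  n_trials_per_condition: 100
  n_practice: 10
analysis:
  design: paired
  first_n: null
  n_permutations: 10000
seed: 7
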