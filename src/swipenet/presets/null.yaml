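# Null mechanism: uniform receiver choice, no responses.  First swipes
# are then an exact draw from the row-permutation null, so CUG p-values
# on this preset should be calibrated.
women:
  n: 127
  activity_mean: 6.2
  activity_dispersion: 1.2
  desirability: lognormal
  desirability_scale: 1.0
  aspiration: 0.0
men:
  n: 497
  activity_mean: 9.0
  activity_dispersion: 1.5
  desirability: normal
  desirability_scale: 0.5
  aspiration: 0.0
recip_intercept: -.inf
recip_slope: 0.0
seed: null
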