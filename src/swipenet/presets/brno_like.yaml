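# Smaller-market preset: ~20% women, right-skewed activity, heavy-tailed
# female desirability, positive male aspiration, gap-dependent reciprocation.
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
  aspiration: 1.0
recip_intercept: -1.0
recip_slope: 1.5
seed: null
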