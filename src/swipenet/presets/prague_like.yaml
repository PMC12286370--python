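# Larger-market preset: ~25% women, higher activity, same mechanism mix.
women:
  n: 578
  activity_mean: 13.5
  activity_dispersion: 0.8
  desirability: lognormal
  desirability_scale: 1.0
  aspiration: 0.0
men:
  n: 1743
  activity_mean: 16.5
  activity_dispersion: 1.2
  desirability: normal
  desirability_scale: 0.5
  aspiration: 1.0
recip_intercept: -1.0
recip_slope: 1.5
seed: null
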