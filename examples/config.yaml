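# Example configuration: overrides merge into the package defaults.
network:
  p: 18
  Jplus:
    E: {E: 15.75}
  nu0: {E: 5.0, I: 4.4}
arousal:
  mode: input_heterogeneity
  delta_H: {E: 0.2, I: 0.0}
stimulus:
  n_stimuli: 5
  A_stim: {E: 0.075, I: 0.0}
simulation:
  dt: 0.00005
  T_trial: 3.5
  t_stim: 1.0
  n_trials_per_stimulus: 30
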