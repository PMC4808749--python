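# Circadian forecasting population: correlated amplitudes, shared phase.
model: circadian
amp_mean: [5.0, 5.0]
amp_cov: [[1.0, 0.95], [0.95, 1.0]]
phase_var: 4.0   # prior phase s.d. 2 h
sigma1: 0.25
sigma2: 0.1
schedule:
  1: [14.0]
  2: [22.0]
t_star: 24.0
n_subjects: 1000
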