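# Simulated population of 20 subjects; individual (-1.6, -2.0) tracked with
# primary-only versus paired forecasting.
model: intercept
variant: bivariate
delta1: 1.0
delta2: 1.0
rho: 0.9
sigma1: 1.4142135623730951  # sqrt(2)
sigma2: 0.7071067811865476  # sqrt(0.5)
n_subjects: 20
theta: [-1.6, -2.0]
m1: 10
m2: 10
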