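# Bivariate intercept BMSE curves over secondary sample size.
model: intercept
variant: bivariate
delta1: 1.0
delta2: 1.0
rho: 0.85
sigma1: 1.0
sigma2: 1.0
m1_values: [0, 1, 2, 5, 10]
m2_max: 20
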