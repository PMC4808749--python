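# Univariate intercept illustration: one subject far from the population mean.
model: intercept
variant: univariate
mu: 0.0
delta: 1.0
sigma: 1.0
theta: 1.4
m: 10
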