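# Design regimes as the between-subjects correlation sweeps 0 -> 1.
model: cost_design
delta1: 1.0
delta2: 1.0
sigma1: 1.0
sigma2: 0.5
c1: 5.0
c2: 1.0
eta_sq: 0.30
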