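# Cost-curve solution types: interior / lower-boundary / upper-boundary
# depending on the primary error s.d.
model: cost_design
delta1: 1.0
delta2: 1.0
rho: 0.85
sigma2: 0.5
c1: 500.0
c2: 100.0
eta_sq: 0.30
sigma1_interior: 1.0
sigma1_lower_boundary: 0.15
sigma1_upper_boundary: 3.0
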