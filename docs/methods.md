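# Methods

## Model family and assumptions

All models share one structure: a subject's responses are
`y = f(t, θ) + ε`, where θ is a subject-specific trait vector drawn from a
Gaussian population distribution `θ ~ N(μ, C_θ)` (the Bayesian prior) and ε
is iid Gaussian measurement error with response-type-specific variance σ_r²
(diagonal error covariance — within-subjects correlation between response
types is assumed negligible and is out of scope). Correlation between a
primary and a secondary response arises solely from the between-subjects
correlation of their trait parameters.

For linear f the posterior is Gaussian and conjugate:
precision `C_θ⁻¹ + H'C_ε⁻¹H`, mean shifted by the precision-weighted
residual. The MMSE prediction of any linear functional `h'θ` is its
posterior mean, and its Bayesian mean squared error (BMSE) — the expected
squared prediction error over noise *and* population — equals `h'Σh` with Σ
the posterior covariance. Computations use Cholesky solves throughout; no
explicit matrix inverses except to materialise Σ for inspection. Posterior
covariance matrices are symmetrised at 1e-10 relative tolerance.
Degenerate priors (|ρ| = 1 or |ω| = 1) are rejected: the prior precision
would not exist. Empty designs are legal and return the prior — iterative
forecasting displays start from zero observations.

## Parameters that matter

| symbol | meaning | units | notes |
|---|---|---|---|
| μ, δ² | population mean, between-subjects variance | response units | prior for each trait |
| σ_r | within-subjects error s.d. of type r | response units | σ_r > 0 |
| ρ, ω | between-subjects correlation of intercepts / slopes | — | the information channel; BMSE depends only on ρ² |
| m₁, m₂ | measurement counts per type | — | continuous inside design maths, integer for real designs |
| c₁, c₂ | cost per observation | currency | opaque scalars |
| η | target root-BMSE | response units | squared internally; design exists only if η² < δ₁² |
| τ_r, τ_d, T | homeostat rise/decay constants, wake duration | h | 24 h schedule period |

## Design optimisation

The accuracy constraint `M(θ̂₁) = η²` eliminates m₁, reducing cost
minimisation to one dimension in m₂. The cost curve has at most one
stationary point m₂⁺ (its second derivative is positive whenever |ρ| < 1),
giving exactly three regimes: primary-only (secondary information too
expensive per unit: `c₂/c₁ > (δ₂²/σ₂²)/(δ₁²/σ₁²)·ρ²`), interior
(m₂ = m₂⁺), and secondary-only (m₂⁺ beyond the feasible bound, which is
finite only when `δ₁²(1−ρ²) ≤ η²`). Two algebraic displays in the source
material are typographically corrupted (the critical point and the interior
m̂₁); the forms used here were re-derived from the cost derivative and are
locked to grid-sweep and dense-constrained-optimiser oracles in the tests
rather than trusted as transcribed. |ρ| is used where the corrupted display
shows ρ: negative correlation carries the same information.

Integer designs: plain rounding of the continuous optimum can miss the
optimum, so the solver searches a ±5 neighbourhood of the rounded solution
plus the two axis candidates, with an optional exhaustive 0..50 grid
(verified to agree on randomized draws).

## Measurement timing

On a repeating schedule the homeostat's wake-onset pressure has the closed
fixed point S₀, and the wake-period curve is approximated by its endpoint
chord. The timing BMSE depends on the m measurement times only through
their mean t̄ and variance s² — the variance uses the population (1/m)
normalisation; with 1/(m−1) the closed form no longer matches the matrix
engine, and a test locks this convention. The BMSE decreases without bound
in s² and is minimised over t̄ at `t*·(σ²/m + δ_α²)/δ_α²`, slightly after
the prediction time. When that optimum exceeds the wake duration T, the
package recommends placing all measurements at T. That rule is exact for
m ≤ 2; for larger m it is supported by a seeded random search (default 10⁵
draws, scaled down from a much larger published search; the draw ranges
cover all variance-component ratios within three orders of magnitude, which
is where the model is sensible).

The bivariate extension evaluates the BMSE through the matrix engine — the
published closed-form display is unavailable, so the engine is ground
truth; tests confirm the claimed sufficiency of (t̄₁, s₁², t̄₂, s₂²). The
optimal mean times are t̄₂ = 0 (secondary data anchor the intercept block)
and a primary mean obtained from the univariate rule with the α₁ prior
variance shrunk by the secondary information,
`t̄₁ = t*·[δ_α₁²((1−ρ²)δ_α₂² + σ₂²/m₂) + (σ₁²/m₁)(δ_α₂² + σ₂²/m₂)] /
[δ_α₁²((1−ρ²)δ_α₂² + σ₂²/m₂)]`; this reconstruction satisfies the m₂ → 0
and ρ = 0 limits and matches grid minimisers exactly at fixed spreads. The
all-at-the-boundary rule *fails* in the bivariate case when the slope
correlation ω exceeds ≈ 0.99 or T is small relative to the slope prior
scales — the search reproduces such counterexamples, and the CLI flags the
regime with a warning recommending numerical optimisation.

## Circadian posterior inference

The sinusoidal model is nonlinear only through the shared phase φ.
Conditional on φ the amplitudes are linear-Gaussian, so the package
integrates them out analytically and marginalises φ on a regular grid
(±8 prior s.d., 1601 points; results are stable from ~800 points). This
yields exact, deterministic posterior means, mixture-of-Gaussian credible
intervals, and a population-level BMSE evaluation that vectorises across
subjects sharing a schedule. The alternative route is a seeded random-walk
Metropolis sampler (proposal scale adapted toward ~30% acceptance during
burn-in, then frozen; default 20 000 draws after 5 000 burn-in — shorter
than the 100 000 used in the original study, which the quadrature oracle
shows is more than sufficient here), with an autocorrelation-based
effective-sample-size diagnostic; chains below a configurable ESS floor are
flagged, never silently accepted. MMSE predictions are posterior means of
the nonlinear functional, not the functional of posterior-mean parameters.
Phase is not wrapped: the prior s.d. is far below the 24 h period.

**Phase-prior convention.** The population phase prior is written N(0, 2)
in the source; whether 2 is a variance or an s.d. is ambiguous there. This
package defaults to **s.d. 2 h (variance 4 h²)**: with the variance-2
reading, the exactly-computed primary-only population BMSE (~0.39) is far
from the published 0.53, while the s.d.-2 reading reproduces it (~0.47 ±
0.02 at N = 1000). The field is named `phase_var` and fully configurable.

**A known discrepancy.** With one secondary observation (σ₂ = 0.1 at
t = 22) the exact bivariate BMSE at t* = 24 is ≈ 0.035–0.04 under either
phase-prior reading — substantially *better* than the published 0.20.
Three independent routes agree: phase-grid quadrature, brute-force
importance sampling, and converged Metropolis chains. The low-noise
secondary measurement pins the shared phase to ≈ 0.09 h, which exact
inference exploits fully. The package reports its own computed value and
does not attempt to reproduce the larger published figure, which could not
be matched by any faithful reading of the model (plausibly an
under-converged sampler in the original numerical experiment).

## Synthetic data

The generators draw subject traits from the stated Gaussian populations and
add iid Gaussian noise at scheduled times — exactly the data-generating
process the models assume. They emulate none of the complications of real
recordings (non-Gaussian tails, missing nights, drifting error variance,
within-subjects error correlation), so passing tests demonstrate
correctness of the inference and design machinery under the model, not
robustness to model violation. Scenario presets fix the illustration
settings used in the docs: shipped as YAML (fig2, fig3, fig4_5, fig6, fig7,
sec9). Every generator takes a mandatory seed and is bit-reproducible; CSV
round-trips preserve full float precision.

## Problem sizes and numerics

Monte-Carlo checks use 10 000 subjects for calibration tests and 1 000 for
the circadian population (matching the published population size), with
agreement asserted within 3 Monte-Carlo standard errors. The boundary
search runs 10⁵ univariate and 10⁴ bivariate draws by default. Closed
forms are held to 1e-10 relative agreement with the matrix engine;
quadrature grids to ~1e-3 absolute stability. λ(m₂) at m₂ = 0 is defined
by its continuous limit 0 so the design formulas hold without branching;
s² = 0 with m ≥ 2 (simultaneous measurements) is allowed. Integer-design
feasibility uses a 1e-9 relative slack on the η² comparison to absorb
rounding in the achieved-BMSE evaluation.

## Limitations

- Within-subjects (error) correlation between response types is not
  modelled; only one secondary response type is supported.
- Heteroscedastic per-subject error and non-Gaussian priors are out of
  scope.
- The bivariate boundary-case timing recommendation is a heuristic outside
  the small-ω / large-T regime; use the numerical search there.
- Priors are inputs: estimating them from raw study data (e.g. by REML
  mixed-effects fitting) is a separate task not performed here.
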