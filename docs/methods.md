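# Methods

## Model and assumptions

The package analyses target association under pseudo-first-order
conditions, `D_tot ≪ P_tot ≪ C_tot`: one searching protein encounters
effectively constant concentrations of probe and competitor sites, so
fluorescence time courses are mono-exponential and `k_app` is linear
in `P_tot`.  The closed-form `k_a` (README) is the exact
mean-first-passage-time rate of the discrete search scheme in the
`D_tot → 0` limit, *without* assuming quasi-equilibrium of nonspecific
binding.  Its ingredients:

- **Sliding** is an unbiased 1-bp random walk with per-direction hop
  rate `D₁` (bp² s⁻¹ ≡ s⁻¹ on a 1-bp lattice), reflecting duplex ends.
- **Nonspecific residence** ends by dissociation (`k_off,N`) or by
  intersegment transfer to any duplex in solution
  (`k_IT,N` × total site-orientation concentration); hopping
  (short-range dissociation/re-association) is folded into `k_off,N`.
  Intra-molecular transfer is neglected (duplexes shorter than the
  persistence length).
- **Orientations**: a monomeric binder sees `φ = 2` orientations per
  site; the target occupies one orientation of one site, and
  wrong-orientation sites are pure traps.  The antenna `S` is counted
  once among the `φL` probe site-orientations, giving the `(φL − S)`
  trapping remainder.
- The antenna size is evaluated as
  `S = [tanh((m−½)u) + tanh((L−m+½)u)] / (2·tanh(u/2))` with
  `u = −ln y`, `cosh u = 1 + λ⁻²/2` — algebraically identical to the
  ratio-of-powers form in `y` but immune to overflow for any
  `(λ, L)`; it is exact at both limits (`S → 1` as `λ → 0`, `S → L`
  as `λ → ∞`).

### A caveat on the range of S

The familiar description `1 < S < 2λ` of the antenna enhancement is
asymptotic.  The exact supremum of `S` over duplex length is
`coth(u/2) = 2λ·(1 + O(λ⁻²))`, which slightly *exceeds* `2λ` for every
finite `λ` (e.g. `S(λ=1, L=10, m=2) = 2.118 > 2`).  Tests assert the
exact bound `S ≤ coth(u/2) ≤ 2λ(1 + 1/(8λ²))` instead.

Similarly, the mid-target reduction `S ≈ 2λ·tanh(L/2λ)` is an
approximation to the exact expression at `m = (L+1)/2`; the
implementation reports the discrepancy rather than assuming it away
(grid-wide below 5% for `λ ≥ 2`, dominated by small-`λ` corners).

## Fitting conventions

- **Length fit** (`k_a` vs probe length at fixed concentrations):
  `τ_N ≡ λ²/D₁`, so `(D₁, λ)` are the two free parameters and the fit
  never references `k_off,N` or `k_IT,N`.  The small concentration
  dependence of `τ_N` across the series (through `φL·D_tot`) is
  thereby absorbed into the effective `λ`; with transfer active this
  makes the convention inexact at the ~0.3% level for the default
  design, which is why exact-recovery tests use a transfer-free truth.
- **Competitor fit** (`k_a` vs `C_tot` at fixed probe): `τ_N`, `λ` and
  `S` are recomputed at every `C_tot` from the full lifetime
  expression; `D₁` is supplied (normally from the length fit).  The
  `without_IT` variant pins `k_IT,N = 0` (nested model).  Designs
  spanning less than 4-fold in `C_tot` are rejected as
  non-identifiable.
- **Joint fit** optimises `(D₁, k_off,N, k_IT,N)` against both series
  with `λ = sqrt(D₁ τ_N)` evaluated at each point's own
  concentrations.
- Objective: unweighted sum of squared `k_a` residuals by default;
  optional `1/se²` weighting.  All positive parameters are optimised
  in natural-log space (positivity by construction) from a
  deterministic 5-per-parameter log-spaced multi-start grid, so fits
  are reproducible without a seed.
- **Uncertainties**: Gauss–Newton covariance at the optimum.  With
  per-point SEs (`weighted=True`) the covariance is `(JᵀJ)⁻¹`
  (known-error convention); otherwise it is scaled by `rss/dof`.  A
  seeded residual bootstrap is available as a cross-check.  A log-SE
  above 2.3 (one decade) flags practical non-identifiability — e.g. a
  length series with no curvature cannot pin `λ`.
- **Titration regression**: `k_app = k_a·P_tot (+ intercept)` by
  weighted least squares.  The intercept is allowed by default (it
  absorbs protein-independent relaxation such as target dissociation);
  the origin-constrained variant is available, and the generators
  demonstrate the bias it incurs when a baseline exists.

## Oracles

- **Splitting-probability solve**: capture probabilities `p_i` (reach
  the target before leaving the chain) satisfy a tridiagonal linear
  system with hop rate `D₁` per direction and leave rate `1/τ_N`;
  `S = Σ p_i`.  The characteristic equation of this system,
  `y + 1/y = 2 + 1/(hop·τ)`, coincides with the closed form's root
  under `λ² = hop·τ`, which freezes the per-direction hop-rate
  convention.
- **Gillespie simulation**: one protein over {free, probe site ×
  orientation, competitor site × orientation} with association at
  `k_on,N` × duplex concentration per site-orientation, sliding,
  dissociation, and transfer landing uniformly on site-orientations
  drawn proportionally to concentration.  `k_a = 1/(MFPT · D_tot)`;
  SE by the delta method from the trajectory ensemble.  The simulation
  is vectorised over trajectories and bit-reproducible per seed;
  trajectories hitting `max_time` are censored, counted, and flag the
  estimate above 1% censoring.
- The closed form deviates from the exact scheme MFPT in proportion to
  `D_tot` (the pseudo-first-order parameter): a dense Markov solve in
  the test suite shows sub-0.1% agreement at `D_tot = 0.5` nM rising
  to ~2% at 50 nM with a 16 µM `K_d,N`.  Simulation comparisons are
  therefore run at `D_tot = 5` nM, `C_tot = 20` nM on a 25-site probe
  (10⁴ trajectories, ~1% SE), inside the regime the closed form
  describes, and kept small enough to run in seconds.

## Synthetic data

Generators reproduce the study design: probe lengths
{33, 48, 63, 88, 113, 143} bp, 28-bp competitor, `C_tot` 0.5–16 µM,
`P_tot` 20–400 nM, `D_tot` 2.5 nM, footprint 9 bp (so the 113-bp probe
has 105 sites and the competitor 20), target at site 2, `φ = 2`.
Default truth near physiological salt: `K_d,N = 16` µM and
`k_off,N = 920` s⁻¹ (measured values at 150 mM KCl), `k_IT,N = 10⁷`
M⁻¹ s⁻¹ (transfer comparable to dissociation at 150 mM, as observed),
and `D₁ = 2.5×10⁶` bp² s⁻¹ chosen so the sliding length at the default
condition equals the measured 38 bp.  Noise is mean-one multiplicative
log-normal at 5% (rate constants are positive with roughly constant
log-scale scatter); additive Gaussian noise models trace intensities.
Every generated object embeds its ground truth and seed, so all test
fixtures are regenerable from configuration alone.

The default ionic-strength laws interpolate the measured `k_off,N`
endpoints and the five tabulated `K_d,N` values, take `k_IT,N` from
3×10⁷ to 10⁷ M⁻¹ s⁻¹ over 40–150 mM, and anchor `D₁` so the sliding
length is 122 bp at 40 mM and 38 bp at 150 mM.  This yields the
observed trend directions (S and η fall, ρ rises with salt).  Note the
implied `k_on,N = k_off,N/K_d,N` *rises* steeply with salt for these
values; the interior-optimum demonstration therefore uses a separately
constructed law set with opposing `ρ` / `k_on,N` trends, and the
experimentally observed optimum at 150 mM KCl is treated as a measured
fact, not asserted as a model output (the per-salt `D₁` and `k_IT,N`
values needed to reconstruct that curve are not tabulated).

What the synthetic data do **not** emulate: instrument dead time,
photobleaching, photon noise, Mg²⁺ effects, and any real heterogeneity
between DNA constructs.  Passing recovery tests therefore shows the
estimators are correct for the stated noise model at the stated
designs, not that real data meet those assumptions.

## Numerical choices

- `λ < 10⁻⁶` returns `S = 1` analytically (known limit; avoids
  degenerate hyperbolic arguments).
- `u = −ln y` is computed via `log1p`, keeping `u ≈ 1/λ` accurate to
  machine precision for `λ` up to 10⁸.
- Levenberg–Marquardt with `ftol = xtol = gtol = 10⁻¹⁵` (residuals of
  magnitude ~10⁸ need tight relative tolerances); non-finite residuals
  during wild multi-starts are clamped.
- The salt optimum is located by grid argmax plus golden-section
  refinement in log-KCl; boundary maxima are flagged unrefined,
  non-unimodal grids warn and return the global grid maximum, and the
  refined value is never allowed below the best grid value.
- Power laws use base-10 logarithms (the slope/intercept pair is
  base-consistent either way; one convention is fixed for
  serialisation).
- Units are strictly molar/bp/seconds inside the library; all
  conversion happens at the CSV boundary, where column headers carry
  mandatory unit suffixes.

## Problem sizes

The test suite and acceptance script use: the 60-point
`(λ, L, m)` oracle grid; 10³ randomised parameter sets for the
algebraic identity; 100 seeded replicates for coverage checks; 10⁴
Gillespie trajectories (≈2 s); and 10⁴-point dense grids for optimum
cross-checks.  These sizes keep the full suite around a minute while
leaving sampling errors far below the asserted tolerances.

## Known limitations

- The length-fit `τ_N ≡ λ²/D₁` convention is exact only when `τ_N` is
  length-independent (transfer-free or fixed concentrations dominate).
- Reported uncertainties are asymptotic (Gauss–Newton) or bootstrap;
  with 6-point designs both are approximate, and the weighted
  known-error convention should be preferred when per-point SEs exist.
- The Gillespie oracle shares the model's state space; it validates
  the closed-form algebra and the first-passage treatment, not the
  physical realism of the scheme (no explicit 3-D diffusion, no
  distinct hopping mode).
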