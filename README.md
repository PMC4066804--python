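# targetsearch

Kinetic analysis of sequence-specific **target search on DNA** by
facilitated diffusion — the process by which a DNA-binding protein
(e.g. a zinc-finger transcription factor) finds one specific site among
a large excess of nonspecific DNA by combining 3-D association,
1-D sliding along the duplex, and direct **intersegment transfer**
between duplexes.

The package is aimed at biophysicists analysing stopped-flow
fluorescence measurements of target association: it extracts apparent
rate constants from time courses, fits the microscopic translocation
parameters from DNA-length and competitor-concentration series, and
explains the observed ionic-strength optimum of search speed.

## The model

For a probe duplex with `L` binding sites (target at site `m`, a
protein footprint of `B` bp gives `L = A − B + 1` sites on an `A`-bp
duplex) at concentration `D_tot`, plus an `M`-site nonspecific
competitor at `C_tot`, the apparent second-order association rate
constant is

    k_a = S / (K_d,N + (φL − S)·D_tot + φM·C_tot) · 1/τ_N

with

    τ_N = 1 / (k_off,N + k_IT,N·(φL·D_tot + φM·C_tot))   nonspecific lifetime
    λ   = sqrt(D₁·τ_N)                                    sliding length (bp)
    S   = S(λ, L, m)                                      antenna size (sites)

where `D₁` is the 1-D sliding diffusion coefficient (bp² s⁻¹),
`k_off,N` the nonspecific dissociation rate, `k_IT,N` the second-order
intersegment-transfer rate, `K_d,N` the per-site nonspecific affinity
and `φ` the number of binding orientations per site (2 for a monomer).
The same expression factorises into physically transparent terms,

    k_a = ρ · η · S · k_on,N ,      k_on,N = k_off,N / K_d,N

with `ρ ∈ (0,1]` the fraction of protein not trapped on nonspecific
sites, `η ≥ 1` the transfer enhancement, and `S ≥ 1` the antenna
enhancement from sites that funnel the protein to the target by
sliding.  Because `S` and `η` fall with salt while `ρ` rises, the
composed `k_a(KCl)` can peak at intermediate (physiological) ionic
strength.

Two independent oracles validate the closed form: a
splitting-probability linear solve on the discrete sliding chain
(antenna size), and a Gillespie first-passage simulation of the full
search scheme (`k_a`).

## Worked example

```python
from targetsearch import AssayCondition, NonspecificParams, decompose

params = NonspecificParams(D1=2.5e6, k_off_N=920.0, K_d_N=16e-6,
                           k_IT_N=1e7, phi=2)
cond = AssayCondition(probe_len_bp=113, competitor_len_bp=28,
                      D_tot=2.5e-9, C_tot=2e-6)
d = decompose(params, cond)
print(f"{d.lambda_bp:.2f} {d.S:.2f} {d.rho:.3f} {d.eta:.3f} {d.k_a:.3g}")
```

prints

```
38.07 39.24 0.166 1.875 7.02e+08
```

i.e. with a 38-bp sliding length the 105-site probe behaves as a
39-site antenna (a 39-fold speed-up), nonspecific trapping retains all
but 16.6% of the protein (a 6-fold slow-down), intersegment transfer
contributes a further 1.9-fold speed-up, and the resulting apparent
rate constant is 7.0×10⁸ M⁻¹ s⁻¹.

The `examples/` directory walks through each capability: the
decomposition, the trace → k_app → k_a pipeline, the length and
competitor fits (including the nested no-transfer comparison), the
ionic-strength profile, and the two oracles.  A thin CLI
(`targetsearch --help`) exposes the same stages for batch use on CSV
tables with unit-suffixed headers.

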