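"""Evaluate the target-search rate constant and its decomposition.

Conditions: 113-bp probe (105 sites, target at site 2), 28-bp
competitor (20 sites), D_tot = 2.5 nM, C_tot = 2 uM, and microscopic
parameters plausible for ~150 mM KCl.
"""

from targetsearch import AssayCondition, NonspecificParams, decompose

params = NonspecificParams(
    D1=2.5e6,       # sliding diffusion coefficient, bp^2/s
    k_off_N=920.0,  # nonspecific dissociation, 1/s
    K_d_N=16e-6,    # per-site nonspecific K_d, M
    k_IT_N=1e7,     # intersegment transfer, 1/(M s)
    phi=2,          # monomer: two orientations per site
)
cond = AssayCondition(
    probe_len_bp=113, competitor_len_bp=28, D_tot=2.5e-9, C_tot=2e-6
)

d = decompose(params, cond)
print(f"sliding length  lambda = {d.lambda_bp:8.2f} bp")
print(f"antenna size    S      = {d.S:8.2f} sites   (x{d.S:.0f} faster than one site)")
print(f"untrapped       rho    = {d.rho:8.3f}        (trapping costs x{1/d.rho:.1f})")
print(f"transfer boost  eta    = {d.eta:8.3f}")
print(f"intrinsic       k_on,N = {d.k_on_N:8.3g} /M/s")
print(f"apparent        k_a    = {d.k_a:8.3g} /M/s  = rho*eta*S*k_on,N")
# k_a is the second-order rate constant a stopped-flow titration would
# measure; rho, eta and S say how much trapping slows it and how much
# sliding ("antenna") and direct inter-duplex transfer speed it up.
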