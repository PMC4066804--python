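"""Stage 2a: sliding parameters from the DNA-length dependence of k_a.

Generates a noisy six-length series (33-143 bp probes) from known
ground truth and fits (D1, lambda).  The asymptote of k_a(L) near
L ~ 2*lambda is what makes the sliding length identifiable.
"""

from targetsearch import (
    GeneratorConfig,
    NonspecificParams,
    fit_length_dependence,
    gen_rate_dataset,
)

truth = NonspecificParams(D1=1.33e6, k_off_N=920.0, K_d_N=16e-6, k_IT_N=0.0)
lam_true = (truth.D1 / truth.k_off_N) ** 0.5

config = GeneratorConfig(params=truth, noise_frac=0.05, seed=42)
data = gen_rate_dataset(config, "length")
for a, ka in zip(data.covariate, data.k_a):
    print(f"{a:4.0f} bp probe   k_a = {ka:.3g} /M/s")

fit = fit_length_dependence(data, weighted=True)
print(f"\nD1     = {fit.estimates['D1']:.3g} +/- {fit.se['D1']:.2g} bp^2/s "
      f"(true {truth.D1:.3g})")
print(f"lambda = {fit.estimates['lambda']:.1f} +/- {fit.se['lambda']:.1f} bp "
      f"(true {lam_true:.1f})")
# lambda = sqrt(D1 * tau_N) is the distance scanned per nonspecific
# binding event; probes much longer than 2*lambda no longer speed up
# the search, which is the curvature the fit exploits.
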