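"""Simulate a birth-weight-style cohort and inspect its latent ground truth.

Draws 50,000 individuals from the structural model with the moderator
variant affecting the exposure (Method-1-compatible conditions), then prints
the observed marginals and the oracle estimands the latent fields make
available: the true complier average causal effect and the Wald-ratio
decomposition into its effect and bias components.
"""

import numpy as np

from hetmr import method1_scenario, simulate_cohort, true_cace, wald_estimand

cfg = method1_scenario(n=50_000, seed=1)
cohort = simulate_cohort(cfg)

print(f"cohort size             : {cohort.n}")
print(f"exposure prevalence     : {cohort.s.mean():.3f}")
print(f"moderator frequency     : {cohort.g.mean():.3f}  (target {cfg.p_g})")
print(f"mean outcome (grams)    : {cohort.y.mean():.1f}")
print(f"outcome SD (grams)      : {cohort.y.std():.1f}")

compliers = (cohort.s_if_g1 == 1) & (cohort.s_if_g0 == 0)
print(f"complier fraction       : {compliers.mean():.3f}")
print(f"true CACE (grams)       : {true_cace(cohort):.1f}")

w = wald_estimand(cfg)
print(f"Wald estimand           : {w.estimand:.1f} = ratio {w.ratio_term:.1f} + bias {w.bias_term:.1f}")
print()
print("The CACE mixes the two group effects (-200 for carriers, -100 for")
print("non-carriers) over compliers' factual genotypes.  The Wald ratio is")
print("far more negative: effect heterogeneity among always-exposed")
print("individuals inflates it, which is why a naive one-variant analysis")
print("with a homogeneity-violating instrument misleads.")
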