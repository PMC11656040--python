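"""Desk-scale power study for detecting a small moderated effect.

Maps the power of both methods to detect a 15 g difference between the
genetic groups over a modest sample-size grid with a reduced replicate
count.  The published-scale conclusion — the RGMEE-based Method 2 needs
roughly 200,000 individuals for 80% power where Method 1 needs about
500,000 — can be reproduced by enlarging the grid and replicate count.
"""

from hetmr import power_curve, shared_scenario

table = power_curve(
    shared_scenario(n=1000, seed=0),
    diffs=[-15.0],
    sample_sizes=[50_000, 100_000, 200_000],
    n_reps=50,
    methods=("method1", "method2"),
    master_seed=9,
)

print(table.round(3).to_string(index=False))
print()
print("Power rises with n and Method 2 dominates for the group difference")
print("at every sample size; +-1.96 x mcse_power gives a 95% Monte-Carlo")
print("band around each entry (50 replicates keeps this example quick).")
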