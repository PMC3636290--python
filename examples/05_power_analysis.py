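"""Monte-Carlo power of the between-arm comparison over an effect grid.

How often does the exact Mann–Whitney test on per-group evidence-score
changes (8 vs 7 groups, alpha .025) detect an arm difference, as a function
of the evidence-attraction gap between arms?  The first cell (no gap) is
the null: its rejection rate estimates the type-I error.
"""

from consensim import compare_protocols, default_behavior, default_design

grid = [
    {"eps_hc": 0.3, "eps_ic": 0.3, "gamma": 0.35},  # null: arms exchangeable
    {"eps_hc": 0.8, "eps_ic": 0.3, "gamma": 0.35},
    {"eps_hc": 1.5, "eps_ic": 0.3, "gamma": 0.35},
]
table = compare_protocols(
    default_design(), default_behavior(), grid, n_replicates=100, seed=7
)
cols = ["eps_hc", "eps_ic", "rejection_rate", "mc_se", "mean_change_gap"]
print(table[cols].round(3).to_string(index=False))
# Rejection stays near the nominal .025 under the null and climbs with the
# between-arm gap — at 15 groups, only large behavioural differences are
# reliably detectable, which is why small consensus trials are underpowered.
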