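"""Compute both group-level outcomes: evidence score and agreement kappa.

The evidence score (in [−1, 1]) measures concordance of a group's chosen
options with graded clinical evidence: 1 means everyone picked the
best-evidenced option, negative values mean answers the evidence argues
against.  Kappa measures chance-corrected within-group agreement.
"""

from consensim import (
    compute_outcome_series,
    default_behavior,
    default_design,
    simulate_trial,
)

trial = simulate_trial(default_design(), default_behavior(), seed=1)
scores = compute_outcome_series(trial.table)

means = (
    scores.groupby(["arm", "scenario_id", "round"])[["evidence_score", "kappa"]]
    .mean()
    .round(2)
)
print(means)
# Both outcomes rise from round 1 to round 3: evidence feedback pulls
# choices toward better-evidenced options, conformity pulls groups together.
# The sick-leave scenario carries no evidence, so only kappa is defined.
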