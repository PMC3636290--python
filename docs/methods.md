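# Methods

## The design being simulated

A two-arm randomized comparison of consensus processes for guideline
development. 120 participants are randomized (forced realized totals 64/56
by default, true 1:1 simple randomization behind a flag) into 8
human-computation (HC) and 7 informal-consensus (IC) groups of eight.
Every participant answers 4 multiple-choice low-back-pain scenarios —
medical imaging, therapeutic options, drug use (each with GRADE-graded
options), and sick leave (no evidence) — at three rounds: before, during,
and after the consensus process.

**HC protocol** (per team of two, per scenario): independent answers
(attempt 1 = round 1); on disagreement the evidence and the teammate's
answer are revealed and each teammate gets exactly one chance to change
(attempt 2 = round 2); the transcript records consensus and elapsed time.
Teams are ranked by consensus count desc, time-limit violations asc, total
time asc, ties by team id. The third, individual round happens only after
the ranking is fixed, so the competition element cannot leak into the final
answers.

**IC protocol** (per group, per scenario): individual round 1; random pair
discussion with the evidence, then individual round 2; moderated full-group
discussion, then individual round 3.

## Opinion-dynamics model

Only outcomes of real trials are observed, never the choice mechanics, so
participant behaviour is modelled minimally. A choice is a categorical draw
over the scenario's options. Three parameters:

* **baseline propensity** — per-scenario option weights, the population's
  prior opinion before any intervention;
* **evidence attraction ε ≥ 0** — after evidence is revealed, draw weights
  are multiplied by exp(ε·points), points being the option's signed
  evidence points (a softmax tilt; a scenario without evidence has all
  points 0 and is unaffected, so only conformity moves its answers);
* **conformity γ ∈ [0, 1]** — the probability of adopting a social anchor
  instead of drawing. At pair stages the anchor is the *canonical choice*
  of the two answers on the table: the one with higher evidence points,
  ties broken by lower option index (so at γ = 1, ε = 0 both teammates move
  to the same option and consensus is certain). At the final round the
  anchor is the group's modal round-2 answer, modal ties broken by lower
  option index.

Response times per attempt are log-normal (median 25 s, σ_log 0.6) summed
per team over attempts; the time limit defaults to 120 s per scenario.
These values are plausible for a two-minute-pressure quiz interface; no
published limit exists, and timing feeds only the game ranking, never the
outcomes.

Setting ε = γ = 0 makes every round an independent baseline draw in both
arms, so the null hypothesis of no arm difference holds *exactly* — the
basis of the type-I calibration test.

### Defaults = study conditions

`default_scenarios()` reconstructs four scenarios with 4 options each (the
original questionnaires were never published; this fixture is synthetic).
`default_behavior()` sets baseline propensities so that round-1 group
evidence scores start slightly negative on imaging (imaging is over-valued
relative to evidence), high on therapy, intermediate on drugs — the
qualitative baseline pattern of such trials. ε defaults to 0.3 and γ to
0.35: with points spanning −4…4, ε = 0.3 gives an 8-fold tilt between
adjacent extremes, enough to move groups markedly between rounds without
saturating round 3 at unanimity (larger ε collapses round-3 variance to
zero, making effect sizes degenerate, which real panels never show).

## Outcome statistics

**Evidence score** E = Σ points(choice)/(n · max points) with points high 4,
moderate 3, low 2, very low 1, negated for evidence-against options, 0 for
ungraded options (ungraded options inside a graded scenario simply score 0).
The denominator uses the maximum *positive* option points, not the range,
so unanimous contra-evidence choices reach −1. Undefined (error, never NaN
silently) for scenarios with no graded option at all; the series builder
emits NaN for those scenarios since the statistic does not exist there.

**Agreement kappa** for one item, n raters: Po = concordant pairs / all
pairs; κ = (Po − Pe)/(1 − Pe). The chance model is pluggable because a
single item cannot identify it: *free-marginal* (Pe = 1/k, the
Brennan–Prediger/Randolph convention) is the default — fixed-marginal
chance is degenerate on a single unanimous item — and *fixed-marginal*
(Fleiss-style Pe = Σ share²) is available; the choice is carried in the
output metadata.

Series values are quantized to 12 decimals so outcomes equal up to
floating-point roundoff rank as exact ties in the downstream tests and
survive text round-trips losslessly.

## Inference

Group outcomes are treated as independent observations (no cluster
adjustment — at 15 groups there is nothing to estimate a cluster model
with). Within-arm change: Cohen's d = |Δmean|/√((s₁²+s₃²)/2), sample SDs;
zero pooled SD raises an error rather than returning ∞. Between arms:
d = (mean HC change − mean IC change)/pooled SD with (n−1)-weighted
pooling; *signed* by default — the direction of an arm difference is the
finding — with a flag for the absolute form. Wilcoxon signed-rank: zeros
dropped, mid-ranks for ties, exact two-sided p = 2·min(P(W≤w), P(W≥w))
capped at 1, computed by generating-function convolution over all 2ⁿ sign
assignments for n ≤ 20. Mann–Whitney: U = #(a>b) + ½·ties; for n+m ≤ 20
the p enumerates all C(n+m, n) labelings, counting those with |U − nm/2| ≥
the observed deviation (ties handled exactly); beyond 20, tie-corrected
normal approximations. The study-sized arms (8 and 7 groups) always take
the exact path. Multiplicity: Bonferroni α/m with m = 2 outcomes per
scenario → .025. Baseline tables use t-distribution 95% CIs.

## The power/recovery study

`compare_protocols` simulates full trials on a grid of (ε_HC, ε_IC, γ),
applies the exact Mann–Whitney test to per-group evidence-score changes on
one graded scenario, and reports rejection fractions with Monte-Carlo SEs.
Cells with ε_HC = ε_IC estimate the type-I error; increasing ε_HC − ε_IC
traces the power curve. Per-cell seeds are spawned from the root seed, so
adding grid cells never reshuffles earlier ones.

## Determinism

One root seed drives everything. Per-group streams are derived by CRC-32
hashing of the group id combined with the root seed, so changing the number
of groups does not reshuffle the draws of the others. Reruns of the
pipeline with the same config are byte-identical, including all persisted
CSV intermediates.

## What the generator does and does not emulate

It reproduces the design's *structure* (arms, group and team sizes, rounds,
consensus mechanics, ranking, timing pressure) and the qualitative
round-wise movement of outcomes. It does not model: utterance content or
moderator behaviour, participant heterogeneity (all share one parameter
set), learning across scenarios, dropout or missing answers, or any
dependence of conformity on who the partner is. Passing tests therefore
show that the statistics and pipeline are correct and calibrated under
this model — not that the model's parameter values describe any particular
human panel.

## Problem sizes used in the checks

Monotonicity of evidence-score change in ε (grid 0, 0.5, 1, 2, γ = 0) and
of kappa change in γ (grid 0, ⅓, ⅔, 1, ε = 0) uses 200 replicates of a
single 8-member group per cell with common random numbers across cells.
Null calibration runs 500 full-trial replicates (15 groups × 4 scenarios)
with both arms at ε = 0.3, γ = 0.35 and requires the between-arm rejection
rate at α = .025 to lie within 3 Monte-Carlo SEs of .025. The oracle
equivalence checks enumerate all sign assignments up to n = 8 and all
labelings up to n + m = 12, and 10⁴ random 8-rater panels for the kappa
pair-counting oracle.

## Known limitations

* The kappa chance model of any given historical analysis is generally
  unrecoverable from printed values; both models are provided, neither is
  claimed to reproduce any specific published table.
* The canonical-choice tie-break injects a mild pro-evidence drift even at
  ε = 0 whenever γ > 0 (the anchor prefers higher-points options). This is
  a deliberate modelling choice — discussion surfaces evidence — but it is
  symmetric across arms, so null calibration is unaffected.
* Exact tests above n = 20 would be expensive; the implementation switches
  to normal approximations there, far beyond any realistic group count in
  this design.
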