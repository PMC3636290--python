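"""End-to-end orchestration: simulate → score → analyze → report.

Every stage persists its output as delimited text so each later stage is
independently re-runnable from the files alone, and every number in the
final report bundle is recomputable from those intermediates.  The report
mirrors the tables a consensus-trial write-up prints: a baseline table
(mean outcome with 95% CI per arm × scenario at round 1), round-wise
trajectory tables, and an effect-size table with within-arm Cohen's d plus
Wilcoxon p and between-arm Cohen's d plus Mann–Whitney p, flagged against a
Bonferroni-adjusted alpha.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_stats import (
    DegenerateDataError,
    between_group_d,
    bonferroni_alpha,
    mann_whitney_u_exact,
    mean_ci95,
    wilcoxon_signed_rank_exact,
    within_group_d,
)
from .scoring import ChanceModel, compute_outcome_series
from .synthetic_panel import (
    BehaviorParams,
    SimulatedTrial,
    TrialDesign,
    default_behavior,
    default_scenarios,
    ranking_frame,
    simulate_trial,
    transcripts_frame,
)
from .trial_model import load_scenarios, validate_trial, write_answers

__all__ = [
    "RunConfig",
    "ReportBundle",
    "load_run_config",
    "analyze_scores",
    "baseline_table",
    "trajectory_table",
    "run_pipeline",
    "compare_protocols",
]

log = logging.getLogger("consensim")


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible pipeline run depends on."""

    seed: int
    out_dir: Path
    design: TrialDesign
    behavior: BehaviorParams
    chance_model: ChanceModel = "free_marginal"
    alpha: float = 0.05
    m_outcomes: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.m_outcomes < 1:
            raise ValueError(f"m_outcomes must be ≥ 1, got {self.m_outcomes}")
        object.__setattr__(self, "out_dir", Path(self.out_dir))


@dataclass
class ReportBundle:
    baseline: pd.DataFrame
    trajectories: pd.DataFrame
    effects: pd.DataFrame
    scores: pd.DataFrame
    metadata: dict


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration.

    Keys: ``seed``, ``out_dir``, optional ``scenarios`` (path to a scenario
    file; the built-in study-shaped set when omitted), optional ``design``
    (n_hc_groups, n_ic_groups, group_size), optional ``behavior`` (any
    :class:`BehaviorParams` field), ``chance_model``, ``alpha``,
    ``m_outcomes``.
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    scenarios = (
        load_scenarios(doc["scenarios"]) if "scenarios" in doc else default_scenarios()
    )
    design_kw = doc.get("design", {})
    design = TrialDesign(scenarios=scenarios, **design_kw)
    behavior_kw = dict(doc.get("behavior", {}))
    base = default_behavior(scenarios)
    if "baseline_propensity" in behavior_kw:
        behavior = BehaviorParams(**behavior_kw)
    else:
        behavior = replace(base, **behavior_kw)
    return RunConfig(
        seed=int(doc.get("seed", 0)),
        out_dir=Path(doc.get("out_dir", "consensim_run")),
        design=design,
        behavior=behavior,
        chance_model=doc.get("chance_model", "free_marginal"),
        alpha=float(doc.get("alpha", 0.05)),
        m_outcomes=int(doc.get("m_outcomes", 2)),
    )


# ---------------------------------------------------------------------------
# Analysis tables


def _round_values(scores: pd.DataFrame, outcome: str, rnd: int) -> pd.DataFrame:
    sub = scores[scores["round"] == rnd]
    return sub.pivot_table(
        index=["arm", "group_id"], columns="scenario_id", values=outcome, aggfunc="first"
    )


def baseline_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Round-1 mean and 95% CI per arm × scenario × outcome."""
    rows = []
    sub = scores[scores["round"] == 1]
    for outcome in ("evidence_score", "kappa"):
        for (arm, sid), grp in sub.groupby(["arm", "scenario_id"]):
            vals = grp[outcome].dropna().to_numpy()
            if vals.size < 2:
                continue
            mean, lo, hi = mean_ci95(vals)
            rows.append(
                {
                    "outcome": outcome,
                    "arm": arm,
                    "scenario_id": sid,
                    "n_groups": vals.size,
                    "mean": mean,
                    "ci95_low": lo,
                    "ci95_high": hi,
                }
            )
    return pd.DataFrame(rows)


def trajectory_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean outcome per arm × scenario × round (the figure-shaped table)."""
    long = scores.melt(
        id_vars=["group_id", "arm", "scenario_id", "round"],
        value_vars=["evidence_score", "kappa"],
        var_name="outcome",
        value_name="value",
    ).dropna(subset=["value"])
    out = (
        long.groupby(["outcome", "arm", "scenario_id", "round"])["value"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"count": "n_groups"})
    )
    return out


def analyze_scores(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    m_outcomes: int = 2,
    signed: bool = True,
) -> pd.DataFrame:
    """Effect sizes and exact tests on round 1 → 3 changes, per scenario.

    For each scenario × outcome: within-arm Cohen's d with an exact Wilcoxon
    signed-rank p per arm, and the between-arm Cohen's d on per-group changes
    with an exact Mann–Whitney p.  ``significant`` flags p below the
    Bonferroni-adjusted level alpha/m_outcomes.  Degenerate cells (zero
    pooled SD) yield NaN effect sizes rather than a crash.
    """
    adj = bonferroni_alpha(alpha, m_outcomes)
    rows = []
    for outcome in ("evidence_score", "kappa"):
        r1 = _round_values(scores, outcome, 1)
        r3 = _round_values(scores, outcome, 3)
        for sid in r1.columns:
            per_arm: dict[str, np.ndarray] = {}
            row: dict = {"outcome": outcome, "scenario_id": sid}
            defined = False
            for arm in ("HC", "IC"):
                if arm not in r1.index.get_level_values("arm"):
                    continue
                v1 = r1.loc[arm][sid].dropna()
                v3 = r3.loc[arm][sid].reindex(v1.index).dropna()
                v1 = v1.reindex(v3.index)
                if len(v1) < 2:
                    continue
                defined = True
                changes = (v3 - v1).to_numpy()
                per_arm[arm] = changes
                try:
                    d_within = within_group_d(v1.to_numpy(), v3.to_numpy())
                except DegenerateDataError:
                    d_within = float("nan")
                wil = wilcoxon_signed_rank_exact(changes)
                row[f"n_{arm.lower()}"] = len(v1)
                row[f"within_d_{arm.lower()}"] = d_within
                row[f"wilcoxon_p_{arm.lower()}"] = wil.p_value
                row[f"within_significant_{arm.lower()}"] = wil.p_value <= adj
            if not defined:
                continue
            if "HC" in per_arm and "IC" in per_arm:
                try:
                    d_between = between_group_d(per_arm["HC"], per_arm["IC"], signed=signed)
                except DegenerateDataError:
                    d_between = float("nan")
                mw = mann_whitney_u_exact(per_arm["HC"], per_arm["IC"])
                row["between_d"] = d_between
                row["mann_whitney_u"] = mw.statistic
                row["mann_whitney_p"] = mw.p_value
                row["between_significant"] = mw.p_value <= adj
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["alpha_adjusted"] = adj
    return out


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Simulate a trial, score it, analyze it, and persist every stage.

    Writes ``answers.csv``, ``transcripts.csv``, ``rankings.csv``,
    ``scores.csv``, ``baseline.csv``, ``trajectories.csv``, ``effects.csv``
    and ``summary.json`` under ``config.out_dir``.  Deterministic given the
    seed: a rerun with the same config reproduces every file byte for byte.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    trial = simulate_trial(config.design, config.behavior, config.seed)
    report = validate_trial(trial.table, group_size=config.design.group_size)
    if not report.is_empty:
        raise RuntimeError(f"stage simulate: generated trial failed validation:\n{report}")
    write_answers(trial.table, out / "answers.csv")
    tf = transcripts_frame(trial.transcripts, teams=trial.team_members)
    tf.to_csv(out / "transcripts.csv", index=False)
    ranking_frame(trial.rankings).to_csv(out / "rankings.csv", index=False)
    log.info(
        "stage=simulate seed=%d records=%d transcripts=%d elapsed=%.2fs",
        config.seed, len(trial.table.frame), len(trial.transcripts), time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    scores = compute_outcome_series(trial.table, chance_model=config.chance_model)
    scores.to_csv(out / "scores.csv", index=False)
    log.info("stage=score rows=%d elapsed=%.2fs", len(scores), time.perf_counter() - t0)

    t0 = time.perf_counter()
    baseline = baseline_table(scores)
    trajectories = trajectory_table(scores)
    effects = analyze_scores(scores, alpha=config.alpha, m_outcomes=config.m_outcomes)
    baseline.to_csv(out / "baseline.csv", index=False)
    trajectories.to_csv(out / "trajectories.csv", index=False)
    effects.to_csv(out / "effects.csv", index=False)
    metadata = {
        "package": "consensim",
        "version": __version__,
        "seed": config.seed,
        "chance_model": config.chance_model,
        "alpha": config.alpha,
        "m_outcomes": config.m_outcomes,
        "alpha_adjusted": bonferroni_alpha(config.alpha, config.m_outcomes),
        "n_hc_groups": config.design.n_hc_groups,
        "n_ic_groups": config.design.n_ic_groups,
        "group_size": config.design.group_size,
        "n_answer_records": int(len(trial.table.frame)),
        "scenarios": [s.scenario_id for s in config.design.scenarios],
    }
    (out / "summary.json").write_text(json.dumps(metadata, indent=2) + "\n", encoding="utf-8")
    log.info("stage=analyze elapsed=%.2fs out=%s", time.perf_counter() - t0, out)
    return ReportBundle(
        baseline=baseline, trajectories=trajectories, effects=effects,
        scores=scores, metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Power / recovery study


def _evidence_changes(trial: SimulatedTrial, scenario_id: str) -> dict[str, np.ndarray]:
    """Per-group evidence-score change (round 3 − round 1), by arm.

    A lean path used inside Monte-Carlo loops; equivalent to running
    :func:`consensim.scoring.compute_outcome_series` and differencing.
    """
    scenario = trial.table.scenario(scenario_id)
    from .scoring import evidence_points, max_option_points

    pts = {o.option_id: evidence_points(o.evidence) for o in scenario.options}
    denom = max_option_points(scenario)
    frame = trial.table.frame
    sub = frame[(frame["scenario_id"] == scenario_id) & frame["round"].isin([1, 3])]
    vals = sub["option_id"].map(pts)
    agg = (
        sub.assign(points=vals)
        .groupby(["arm", "group_id", "round"])["points"]
        .mean()
        .unstack("round")
    )
    change = (agg[3] - agg[1]) / denom
    return {
        arm: change.loc[arm].to_numpy()
        for arm in change.index.get_level_values("arm").unique()
    }


def compare_protocols(
    design: TrialDesign,
    behavior: BehaviorParams,
    grid: Sequence[Mapping[str, float]],
    n_replicates: int,
    seed: int,
    scenario_id: str | None = None,
    alpha: float = 0.05,
    m_outcomes: int = 2,
) -> pd.DataFrame:
    """Monte-Carlo rejection rates of the between-arm test over a parameter grid.

    Each grid cell is a mapping with keys ``eps_hc``, ``eps_ic`` and
    ``gamma``.  Per replicate, a full trial is simulated with arm-specific
    evidence attraction, per-group evidence-score changes (round 3 − 1) on
    one evidence-bearing scenario are compared between arms with the exact
    Mann–Whitney test, and a rejection is counted when p falls at or below
    the Bonferroni-adjusted alpha.  Returns one row per cell with the
    rejection fraction and its Monte-Carlo standard error (NaN when a single
    replicate makes an SE meaningless).

    With ``eps_hc == eps_ic`` and a common gamma the arms are exchangeable
    and the rejection rate estimates the test's type-I error.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be ≥ 1")
    if scenario_id is None:
        scenario_id = next(s.scenario_id for s in design.scenarios if s.has_evidence)
    adj = bonferroni_alpha(alpha, m_outcomes)
    root = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    rows = []
    for cell_idx, cell in enumerate(grid):
        eps_hc = float(cell["eps_hc"])
        eps_ic = float(cell["eps_ic"])
        gamma = float(cell.get("gamma", behavior.conformity))
        p_hc = replace(behavior, evidence_attraction=eps_hc, conformity=gamma)
        p_ic = replace(behavior, evidence_attraction=eps_ic, conformity=gamma)
        child = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(cell_idx,)
        ).generate_state(n_replicates, dtype=np.uint32) >> np.uint32(1)
        n_reject = 0
        mean_change_gap = 0.0
        for r in range(n_replicates):
            trial = simulate_trial(design, p_hc, int(child[r]), params_ic=p_ic)
            changes = _evidence_changes(trial, scenario_id)
            res = mann_whitney_u_exact(changes["HC"], changes["IC"])
            n_reject += res.p_value <= adj
            mean_change_gap += float(changes["HC"].mean() - changes["IC"].mean())
        frac = n_reject / n_replicates
        se = (
            float(np.sqrt(frac * (1 - frac) / n_replicates))
            if n_replicates > 1
            else float("nan")
        )
        rows.append(
            {
                "eps_hc": eps_hc,
                "eps_ic": eps_ic,
                "gamma": gamma,
                "scenario_id": scenario_id,
                "n_replicates": n_replicates,
                "rejection_rate": frac,
                "mc_se": se,
                "mean_change_gap": mean_change_gap / n_replicates,
                "alpha_adjusted": adj,
            }
        )
        log.info(
            "power cell eps_hc=%.2f eps_ic=%.2f gamma=%.2f reject=%.3f",
            eps_hc, eps_ic, gamma, frac,
        )
    return pd.DataFrame(rows)
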