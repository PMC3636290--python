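"""Seeded simulator of a randomized consensus-method trial.

The simulated experiment mirrors a two-arm design: participants are
randomized to a game-based *human computation* (HC) arm or an *informal
consensus* (IC) arm, grouped into panels of eight, and answer multiple-choice
clinical scenarios at three rounds.

HC protocol (per team of two, per scenario): both teammates answer
independently (attempt 1 = round 1).  On disagreement the evidence for each
option and the teammate's answer are revealed and each teammate gets exactly
one chance to change their answer (attempt 2 = round 2); the transcript
records whether consensus was reached and the elapsed time against a time
limit.  Teams are ranked by consensus count, then time-limit violations,
then total time.  After the ranking — outside the game — every participant
answers a third time individually.

IC protocol (per group of eight, per scenario): individual round 1, pair
discussion with evidence then individual round 2, moderated full-group
discussion then individual round 3.

Opinion dynamics
----------------
Unobserved participant behaviour is modelled with three knobs:

* ``baseline_propensity`` — per-scenario categorical weights over options,
  the population's prior opinion;
* ``evidence_attraction`` (ε ≥ 0) — once evidence is revealed, draw weights
  are multiplied by exp(ε · points) where points are the signed evidence
  points of each option (a softmax tilt; scenarios without evidence are
  unaffected);
* ``conformity`` (γ ∈ [0, 1]) — probability of adopting a social anchor
  instead of drawing: at pair stages the anchor is the canonical choice of
  the two answers on the table (higher evidence points, then lower option
  index), at the final round it is the group's modal round-2 answer (modal
  ties broken by lower option index).

With ε = γ = 0 every round is a fresh independent draw from the baseline,
which makes the null hypothesis of no between-arm difference exactly true —
the calibration case for the downstream tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import evidence_points
from .trial_model import (
    AnswerTable,
    ANSWER_COLUMNS,
    Arm,
    AnswerOption,
    EvidenceMark,
    Grade,
    Direction,
    Group,
    Scenario,
)

__all__ = [
    "BehaviorParams",
    "TeamTranscript",
    "RankingEntry",
    "Ranking",
    "TrialDesign",
    "SimulatedTrial",
    "default_scenarios",
    "default_behavior",
    "default_design",
    "randomize_participants",
    "simulate_hc_scenario",
    "simulate_ic_rounds",
    "rank_teams",
    "simulate_trial",
    "transcripts_frame",
    "ranking_frame",
]


@dataclass(frozen=True)
class BehaviorParams:
    """Tunable opinion-dynamics parameters of the simulated population.

    ``baseline_propensity`` maps scenario_id to option weights (same order as
    the scenario's options).  Response times per answer attempt are
    log-normal with median ``response_time_median_s`` seconds and log-scale
    spread ``response_time_sigma``; a team exceeds the limit when its summed
    attempt times pass ``time_limit_s``.
    """

    baseline_propensity: Mapping[str, Sequence[float]]
    evidence_attraction: float = 0.3
    conformity: float = 0.35
    response_time_median_s: float = 25.0
    response_time_sigma: float = 0.6
    time_limit_s: float = 120.0

    def __post_init__(self) -> None:
        if self.evidence_attraction < 0:
            raise ValueError(f"evidence_attraction must be ≥ 0, got {self.evidence_attraction}")
        if not 0.0 <= self.conformity <= 1.0:
            raise ValueError(f"conformity must be in [0, 1], got {self.conformity}")
        if self.response_time_median_s <= 0 or self.time_limit_s <= 0:
            raise ValueError("time parameters must be positive")
        for sid, w in self.baseline_propensity.items():
            arr = np.asarray(w, dtype=float)
            if (arr < 0).any() or arr.sum() <= 0:
                raise ValueError(
                    f"propensity weights for {sid!r} must be non-negative with positive sum"
                )

    def weights_for(self, scenario: Scenario) -> np.ndarray:
        w = np.asarray(self.baseline_propensity[scenario.scenario_id], dtype=float)
        if w.size != len(scenario.options):
            raise ValueError(
                f"scenario {scenario.scenario_id!r}: {w.size} weights for "
                f"{len(scenario.options)} options"
            )
        return w / w.sum()


@dataclass(frozen=True)
class TeamTranscript:
    """One HC team's consensus attempt(s) on one scenario."""

    team_id: str
    scenario_id: str
    attempt1: tuple[str, str]
    consensus_after_attempt1: bool
    attempt2: tuple[str, str] | None
    consensus_final: bool
    elapsed_seconds: float
    limit_exceeded: bool

    def __post_init__(self) -> None:
        if self.consensus_after_attempt1 != (self.attempt2 is None):
            raise ValueError("attempt2 must be present exactly when attempt 1 failed")
        final = self.attempt1 if self.attempt2 is None else self.attempt2
        if self.consensus_final != (final[0] == final[1]):
            raise ValueError("consensus_final inconsistent with the final attempt")


@dataclass(frozen=True)
class RankingEntry:
    team_id: str
    consensus_count: int
    total_time: float
    exceed_count: int


Ranking = tuple[RankingEntry, ...]


@dataclass(frozen=True)
class TrialDesign:
    """Shape of the experiment: arm sizes, group size, and the scenario set."""

    scenarios: tuple[Scenario, ...]
    n_hc_groups: int = 8
    n_ic_groups: int = 7
    group_size: int = 8

    @property
    def n_participants(self) -> int:
        return (self.n_hc_groups + self.n_ic_groups) * self.group_size


@dataclass
class SimulatedTrial:
    table: AnswerTable
    transcripts: list[TeamTranscript]
    rankings: dict[str, Ranking]
    unassigned: tuple[str, ...] = ()

    @property
    def team_members(self) -> dict[str, tuple[str, str]]:
        """Map team_id (``<group>-T<k>``) to the pair of participant ids."""
        out = {}
        for g in self.table.groups:
            for k, team in enumerate(g.teams):
                out[f"{g.group_id}-T{k + 1}"] = tuple(team)
        return out


# ---------------------------------------------------------------------------
# Study-shaped defaults

def default_scenarios() -> tuple[Scenario, ...]:
    """Four lower-back-pain scenarios: three evidence-graded, one without.

    The option lists are a synthetic reconstruction (the original
    questionnaires were not published); grades follow mainstream low-back-pain
    guidance so that each graded scenario has a unique best-evidenced option.
    """

    def opt(oid: str, label: str, grade: str, direction: str) -> AnswerOption:
        return AnswerOption(oid, label, EvidenceMark(Grade(grade), Direction(direction)))

    return (
        Scenario(
            "imaging",
            "Medical imaging for acute low back pain",
            (
                opt("no_imaging", "No routine imaging", "high", "pro"),
                opt("xray", "Plain radiography", "low", "contra"),
                opt("mri", "MRI scan", "moderate", "contra"),
                opt("ct", "CT scan", "low", "contra"),
            ),
        ),
        Scenario(
            "therapy",
            "Therapeutic options for acute low back pain",
            (
                opt("stay_active", "Advise to stay active", "high", "pro"),
                opt("exercise", "Supervised exercise therapy", "moderate", "pro"),
                opt("bed_rest", "Prescribe bed rest", "moderate", "contra"),
                opt("manipulation", "Spinal manipulation", "very_low", "pro"),
            ),
        ),
        Scenario(
            "drugs",
            "Drug treatment for acute low back pain",
            (
                opt("nsaid", "NSAID course", "high", "pro"),
                opt("paracetamol", "Paracetamol first", "moderate", "pro"),
                opt("opioid", "Strong opioids", "moderate", "contra"),
                opt("relaxant", "Muscle relaxants", "low", "pro"),
            ),
        ),
        Scenario(
            "sick_leave",
            "Sick leave for acute low back pain",
            (
                opt("none", "No sick leave", "absent", "none"),
                opt("days", "A few days off work", "absent", "none"),
                opt("weeks", "One to two weeks off work", "absent", "none"),
                opt("until_free", "Off work until pain-free", "absent", "none"),
            ),
        ),
    )


def default_behavior(scenarios: Sequence[Scenario] | None = None) -> BehaviorParams:
    """Population behaviour emulating the observed trial conditions.

    Baseline propensities are chosen so that group evidence scores start
    slightly negative on the imaging scenario (the population over-values
    imaging), high on the therapy scenario, and intermediate on drugs —
    the qualitative baseline pattern of the modelled study.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    weights = {
        "imaging": [0.25, 0.30, 0.30, 0.15],
        "therapy": [0.60, 0.25, 0.05, 0.10],
        "drugs": [0.25, 0.30, 0.15, 0.30],
        "sick_leave": [0.30, 0.40, 0.20, 0.10],
    }
    known = {s.scenario_id for s in scenarios}
    props = {
        sid: w for sid, w in weights.items() if sid in known
    }
    # uniform prior over options for scenarios outside the default set
    for s in scenarios:
        if s.scenario_id not in props:
            props[s.scenario_id] = [1.0] * len(s.options)
    return BehaviorParams(baseline_propensity=props)


def default_design() -> TrialDesign:
    return TrialDesign(scenarios=default_scenarios())


# ---------------------------------------------------------------------------
# Randomization


def randomize_participants(
    n_participants: int,
    group_size: int = 8,
    arm_counts: tuple[int, int] | None = None,
    seed: int | np.random.Generator = 0,
    simple: bool = False,
) -> tuple[tuple[Group, ...], tuple[str, ...]]:
    """Randomly assign participants to HC and IC groups.

    By default the realized arm totals are *forced* to ``arm_counts``
    (defaults to a balanced split rounded down to whole groups), which
    reproduces a realized design exactly; ``simple=True`` instead flips a
    fair coin per participant (true simple 1:1 randomization) and forms as
    many whole groups per arm as the realized counts allow.  Participants
    left over after whole-group formation are returned as unassigned
    observers.  HC groups are partitioned into four disjoint teams of two by
    the shuffled order (the envelope-number procedure).  Deterministic given
    the seed.
    """
    if group_size % 2 != 0:
        raise ValueError(f"group_size must be even for pair play, got {group_size}")
    if n_participants < group_size:
        raise ValueError("need at least one group's worth of participants")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [f"p{i:03d}" for i in range(1, n_participants + 1)]
    order = rng.permutation(n_participants)
    shuffled = [ids[i] for i in order]
    if simple:
        coins = rng.integers(0, 2, size=n_participants)
        hc_pool = [p for p, c in zip(shuffled, coins) if c == 0]
        ic_pool = [p for p, c in zip(shuffled, coins) if c == 1]
        n_hc = (len(hc_pool) // group_size) * group_size
        n_ic = (len(ic_pool) // group_size) * group_size
        unassigned = tuple(hc_pool[n_hc:] + ic_pool[n_ic:])
        hc_pool, ic_pool = hc_pool[:n_hc], ic_pool[:n_ic]
    else:
        if arm_counts is None:
            half = ((n_participants // 2) // group_size) * group_size
            arm_counts = (half, ((n_participants - half) // group_size) * group_size)
        n_hc, n_ic = arm_counts
        if n_hc % group_size or n_ic % group_size:
            raise ValueError(f"arm counts {arm_counts} must be multiples of group_size")
        if n_hc + n_ic > n_participants:
            raise ValueError(f"arm counts {arm_counts} exceed n_participants={n_participants}")
        hc_pool = shuffled[:n_hc]
        ic_pool = shuffled[n_hc : n_hc + n_ic]
        unassigned = tuple(shuffled[n_hc + n_ic :])
    groups: list[Group] = []
    for k in range(0, len(hc_pool), group_size):
        members = tuple(hc_pool[k : k + group_size])
        teams = tuple((members[i], members[i + 1]) for i in range(0, group_size, 2))
        groups.append(Group(f"HC{k // group_size + 1:02d}", Arm.HC, members, teams))
    for k in range(0, len(ic_pool), group_size):
        members = tuple(ic_pool[k : k + group_size])
        groups.append(Group(f"IC{k // group_size + 1:02d}", Arm.IC, members))
    return tuple(groups), unassigned


# ---------------------------------------------------------------------------
# Opinion-dynamics primitives


def _scenario_points(scenario: Scenario) -> np.ndarray:
    if not scenario.has_evidence:
        return np.zeros(len(scenario.options))
    return np.array([evidence_points(o.evidence) for o in scenario.options], dtype=float)


def _tilted_weights(scenario: Scenario, params: BehaviorParams) -> np.ndarray:
    """Baseline propensity re-weighted by revealed evidence (softmax tilt)."""
    w = params.weights_for(scenario) * np.exp(
        params.evidence_attraction * _scenario_points(scenario)
    )
    return w / w.sum()


def _canonical_choice(scenario: Scenario, a: str, b: str) -> str:
    """Anchor option of a disagreeing pair: higher points, then lower index."""
    pts = _scenario_points(scenario)
    ids = scenario.option_ids
    ia, ib = ids.index(a), ids.index(b)
    if pts[ia] != pts[ib]:
        return a if pts[ia] > pts[ib] else b
    return a if ia <= ib else b


def _modal_option(scenario: Scenario, choices: Sequence[str]) -> str:
    """Most frequent choice; modal ties broken by lower option index."""
    ids = scenario.option_ids
    counts = np.zeros(len(ids), dtype=int)
    for c in choices:
        counts[ids.index(c)] += 1
    return ids[int(np.argmax(counts))]  # argmax takes the first (lowest-index) max


def _draw_option(scenario: Scenario, weights: np.ndarray, rng: np.random.Generator) -> str:
    return scenario.option_ids[int(rng.choice(len(weights), p=weights))]


def _draw_time(params: BehaviorParams, rng: np.random.Generator) -> float:
    return float(
        rng.lognormal(np.log(params.response_time_median_s), params.response_time_sigma)
    )


# ---------------------------------------------------------------------------
# HC protocol


@dataclass(frozen=True)
class HCScenarioResult:
    transcript: TeamTranscript
    round1: dict[str, str]
    round2: dict[str, str]


def simulate_hc_scenario(
    team: tuple[str, str],
    scenario: Scenario,
    params: BehaviorParams,
    rng: np.random.Generator,
    team_id: str | None = None,
) -> HCScenarioResult:
    """One HC team playing one scenario.

    Attempt 1 is an independent baseline draw per teammate (these are also
    the round-1 answers).  On disagreement the evidence is revealed and each
    teammate, independently, either adopts the pair's canonical choice (with
    probability γ) or re-draws from the evidence-tilted propensities.  The
    transcript sums one response-time draw per attempt and flags elapsed
    time beyond the limit.
    """
    base = params.weights_for(scenario)
    a1 = _draw_option(scenario, base, rng)
    b1 = _draw_option(scenario, base, rng)
    elapsed = _draw_time(params, rng)
    round1 = {team[0]: a1, team[1]: b1}
    if a1 == b1:
        transcript = TeamTranscript(
            team_id=team_id or f"{team[0]}+{team[1]}",
            scenario_id=scenario.scenario_id,
            attempt1=(a1, b1),
            consensus_after_attempt1=True,
            attempt2=None,
            consensus_final=True,
            elapsed_seconds=elapsed,
            limit_exceeded=elapsed > params.time_limit_s,
        )
        return HCScenarioResult(transcript, round1, dict(round1))
    tilted = _tilted_weights(scenario, params)
    anchor = _canonical_choice(scenario, a1, b1)
    a2 = anchor if rng.random() < params.conformity else _draw_option(scenario, tilted, rng)
    b2 = anchor if rng.random() < params.conformity else _draw_option(scenario, tilted, rng)
    elapsed += _draw_time(params, rng)
    transcript = TeamTranscript(
        team_id=team_id or f"{team[0]}+{team[1]}",
        scenario_id=scenario.scenario_id,
        attempt1=(a1, b1),
        consensus_after_attempt1=False,
        attempt2=(a2, b2),
        consensus_final=a2 == b2,
        elapsed_seconds=elapsed,
        limit_exceeded=elapsed > params.time_limit_s,
    )
    return HCScenarioResult(transcript, round1, {team[0]: a2, team[1]: b2})


def _final_round(
    scenario: Scenario,
    round2: Mapping[str, str],
    params: BehaviorParams,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Individual final re-rating with conformity toward the group mode."""
    tilted = _tilted_weights(scenario, params)
    mode = _modal_option(scenario, list(round2.values()))
    out = {}
    for pid in round2:
        if rng.random() < params.conformity:
            out[pid] = mode
        else:
            out[pid] = _draw_option(scenario, tilted, rng)
    return out


# ---------------------------------------------------------------------------
# IC protocol


def simulate_ic_rounds(
    group: Group,
    scenario: Scenario,
    params: BehaviorParams,
    rng: np.random.Generator,
    teams: Sequence[tuple[str, str]] | None = None,
) -> dict[int, dict[str, str]]:
    """Three individual rating rounds of one IC group on one scenario.

    Round 1: independent baseline draws.  Round 2: after pair discussion of
    the evidence, each participant either adopts the pair's canonical choice
    (probability γ) or re-draws evidence-tilted.  Round 3: after the
    moderated full-group meeting, conformity pulls toward the group's modal
    round-2 answer.  ``teams`` are the discussion pairs formed after round 1;
    when omitted a random pairing is drawn.
    """
    members = list(group.participant_ids)
    if teams is None:
        if group.teams:
            teams = group.teams
        else:
            order = [members[i] for i in rng.permutation(len(members))]
            teams = [(order[i], order[i + 1]) for i in range(0, len(order), 2)]
    base = params.weights_for(scenario)
    round1 = {pid: _draw_option(scenario, base, rng) for pid in members}
    tilted = _tilted_weights(scenario, params)
    round2: dict[str, str] = {}
    for a, b in teams:
        anchor = _canonical_choice(scenario, round1[a], round1[b])
        for pid in (a, b):
            if rng.random() < params.conformity:
                round2[pid] = anchor
            else:
                round2[pid] = _draw_option(scenario, tilted, rng)
    round3 = _final_round(scenario, round2, params, rng)
    return {1: round1, 2: round2, 3: round3}


# ---------------------------------------------------------------------------
# Ranking


def rank_teams(transcripts: Sequence[TeamTranscript]) -> Ranking:
    """Rank one group's teams by the game's competition key.

    Sort key: consensus count descending, time-limit violations ascending,
    total time ascending; exact ties fall back to team_id order.  Every team
    must have a transcript for every scenario that any team played.
    """
    if not transcripts:
        raise ValueError("no transcripts to rank")
    by_team: dict[str, list[TeamTranscript]] = {}
    for t in transcripts:
        by_team.setdefault(t.team_id, []).append(t)
    scenario_ids = {t.scenario_id for t in transcripts}
    for team_id, ts in by_team.items():
        missing = scenario_ids - {t.scenario_id for t in ts}
        if missing:
            raise ValueError(f"team {team_id!r} missing transcript(s) for {sorted(missing)}")
    entries = [
        RankingEntry(
            team_id=team_id,
            consensus_count=sum(t.consensus_final for t in ts),
            total_time=sum(t.elapsed_seconds for t in ts),
            exceed_count=sum(t.limit_exceeded for t in ts),
        )
        for team_id, ts in sorted(by_team.items())
    ]
    entries.sort(key=lambda e: (-e.consensus_count, e.exceed_count, e.total_time, e.team_id))
    return tuple(entries)


# ---------------------------------------------------------------------------
# Full trial


def _group_rng(root_seed: int, group_id: str) -> np.random.Generator:
    """Per-group stream: stable hash of group_id spawned off the root seed.

    Adding or removing groups never reshuffles the draws of other groups.
    """
    h = zlib.crc32(group_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng([int(root_seed) & 0x7FFFFFFF, h])


def simulate_trial(
    design: TrialDesign,
    params: BehaviorParams,
    seed: int,
    n_participants: int | None = None,
    simple_randomization: bool = False,
    params_ic: BehaviorParams | None = None,
) -> SimulatedTrial:
    """Run the full randomized experiment and return all artefacts.

    The answer table contains rounds 1–3 for every participant × scenario
    (HC round-3 answers are generated only after the team ranking is
    determined, so the competition cannot leak into the final round).
    ``params_ic`` lets the IC arm follow different behaviour than the HC arm
    (for power studies of arm-specific effects); by default both arms share
    ``params``.  Reproducible: identical inputs give identical output.
    """
    arm_counts = (
        design.n_hc_groups * design.group_size,
        design.n_ic_groups * design.group_size,
    )
    n = n_participants if n_participants is not None else design.n_participants
    groups, unassigned = randomize_participants(
        n,
        group_size=design.group_size,
        arm_counts=None if simple_randomization else arm_counts,
        seed=np.random.default_rng([int(seed) & 0x7FFFFFFF, 0]),
        simple=simple_randomization,
    )
    ic_params = params_ic if params_ic is not None else params
    rows: list[tuple] = []
    transcripts: list[TeamTranscript] = []
    rankings: dict[str, Ranking] = {}

    def add(group: Group, sid: str, rnd: int, answers: Mapping[str, str]) -> None:
        for pid in group.participant_ids:
            if pid in answers:
                rows.append((pid, group.group_id, group.arm.value, sid, rnd, answers[pid]))

    for group in groups:
        rng = _group_rng(seed, group.group_id)
        if group.arm is Arm.HC:
            group_transcripts: list[TeamTranscript] = []
            round2_by_scenario: dict[str, dict[str, str]] = {}
            for scenario in design.scenarios:
                r2: dict[str, str] = {}
                for k, team in enumerate(group.teams):
                    res = simulate_hc_scenario(
                        team, scenario, params, rng,
                        team_id=f"{group.group_id}-T{k + 1}",
                    )
                    group_transcripts.append(res.transcript)
                    add(group, scenario.scenario_id, 1, res.round1)
                    r2.update(res.round2)
                add(group, scenario.scenario_id, 2, r2)
                round2_by_scenario[scenario.scenario_id] = r2
            rankings[group.group_id] = rank_teams(group_transcripts)
            transcripts.extend(group_transcripts)
            # final individual round, after the ranking is on the board
            for scenario in design.scenarios:
                r3 = _final_round(scenario, round2_by_scenario[scenario.scenario_id], params, rng)
                add(group, scenario.scenario_id, 3, r3)
        else:
            members = list(group.participant_ids)
            order = [members[i] for i in rng.permutation(len(members))]
            pairs = [(order[i], order[i + 1]) for i in range(0, len(order), 2)]
            for scenario in design.scenarios:
                rounds = simulate_ic_rounds(group, scenario, ic_params, rng, teams=pairs)
                for rnd, answers in rounds.items():
                    add(group, scenario.scenario_id, rnd, answers)

    frame = pd.DataFrame(rows, columns=ANSWER_COLUMNS)
    table = AnswerTable(frame=frame, scenarios=design.scenarios, groups=groups)
    return SimulatedTrial(
        table=table, transcripts=transcripts, rankings=rankings, unassigned=unassigned
    )


# ---------------------------------------------------------------------------
# Tabular views


def transcripts_frame(transcripts: Sequence[TeamTranscript], teams: Mapping[str, tuple[str, str]] | None = None) -> pd.DataFrame:
    """Long-format transcript table: one row per (attempt, seat)."""
    rows = []
    for t in transcripts:
        attempts = [(1, t.attempt1, t.consensus_after_attempt1)]
        if t.attempt2 is not None:
            attempts.append((2, t.attempt2, t.consensus_final))
        members = teams.get(t.team_id) if teams else None
        for attempt_no, pair, consensus in attempts:
            for seat, option_id in enumerate(pair):
                pid = members[seat] if members else f"seat{seat + 1}"
                rows.append(
                    {
                        "team_id": t.team_id,
                        "scenario_id": t.scenario_id,
                        "attempt": attempt_no,
                        "participant_id": pid,
                        "option_id": option_id,
                        "consensus": consensus,
                        "elapsed_seconds": t.elapsed_seconds,
                        "limit_exceeded": t.limit_exceeded,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "team_id", "scenario_id", "attempt", "participant_id", "option_id",
            "consensus", "elapsed_seconds", "limit_exceeded",
        ],
    )


def ranking_frame(rankings: Mapping[str, Ranking]) -> pd.DataFrame:
    rows = []
    for gid, ranking in sorted(rankings.items()):
        for place, e in enumerate(ranking, start=1):
            rows.append(
                {
                    "group_id": gid,
                    "place": place,
                    "team_id": e.team_id,
                    "consensus_count": e.consensus_count,
                    "exceed_count": e.exceed_count,
                    "total_time": e.total_time,
                }
            )
    return pd.DataFrame(
        rows, columns=["group_id", "place", "team_id", "consensus_count", "exceed_count", "total_time"]
    )
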