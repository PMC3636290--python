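"""The trial simulator: randomization, protocols, ranking, determinism."""

import numpy as np
import pandas as pd
import pytest

from consensim.scoring import compute_outcome_series
from consensim.synthetic_panel import (
    BehaviorParams,
    TeamTranscript,
    TrialDesign,
    default_behavior,
    default_scenarios,
    randomize_participants,
    rank_teams,
    simulate_hc_scenario,
    simulate_ic_rounds,
    simulate_trial,
    transcripts_frame,
    RankingEntry,
)
from consensim.trial_model import Arm, Group, validate_trial


def uniform_params(scenarios, **kw):
    props = {s.scenario_id: [1.0] * len(s.options) for s in scenarios}
    return BehaviorParams(baseline_propensity=props, **kw)


class TestRandomization:
    def test_study_realized_design(self):
        groups, unassigned = randomize_participants(120, 8, arm_counts=(64, 56), seed=1)
        arms = [g.arm for g in groups]
        assert arms.count(Arm.HC) == 8 and arms.count(Arm.IC) == 7
        assert unassigned == ()
        for g in groups:
            assert len(g.participant_ids) == 8
            if g.arm is Arm.HC:
                assert len(g.teams) == 4
                assert sorted(p for t in g.teams for p in t) == sorted(g.participant_ids)

    def test_leftover_participants_become_observers(self):
        groups, unassigned = randomize_participants(123, 8, arm_counts=(64, 56), seed=1)
        assert len(unassigned) == 3
        assigned = {p for g in groups for p in g.participant_ids}
        assert assigned.isdisjoint(unassigned)

    def test_deterministic_given_seed(self):
        a = randomize_participants(120, 8, arm_counts=(64, 56), seed=42)
        b = randomize_participants(120, 8, arm_counts=(64, 56), seed=42)
        assert a == b

    def test_odd_group_size_rejected(self):
        with pytest.raises(ValueError, match="even"):
            randomize_participants(21, 7, seed=0)

    def test_simple_randomization_flag(self):
        groups, unassigned = randomize_participants(120, 8, seed=5, simple=True)
        total = sum(len(g.participant_ids) for g in groups) + len(unassigned)
        assert total == 120


class TestHCScenario:
    def test_full_conformity_no_evidence_reaches_consensus(self, ungraded_scenario, rng):
        # γ=1, ε=0: both teammates adopt the pair's canonical choice
        params = uniform_params([ungraded_scenario], evidence_attraction=0.0, conformity=1.0)
        saw_disagreement = False
        for _ in range(50):
            res = simulate_hc_scenario(("a", "b"), ungraded_scenario, params, rng)
            assert res.transcript.consensus_final
            saw_disagreement |= not res.transcript.consensus_after_attempt1
        assert saw_disagreement  # the limit case actually exercised attempt 2

    def test_strong_evidence_attracts_both(self, graded_scenario, rng):
        # ε large, γ=0: attempt 2 lands on the unique max-evidence option
        params = uniform_params([graded_scenario], evidence_attraction=8.0, conformity=0.0)
        hits = trials = 0
        for _ in range(1000):
            res = simulate_hc_scenario(("a", "b"), graded_scenario, params, rng)
            if res.transcript.attempt2 is not None:
                trials += 1
                hits += res.transcript.attempt2 == ("best", "best")
        assert trials > 100
        assert hits / trials >= 0.99

    def test_degenerate_propensity_always_agrees(self, graded_scenario, rng):
        params = BehaviorParams(
            baseline_propensity={"graded": [1.0, 0.0, 0.0, 0.0]}
        )
        for _ in range(20):
            res = simulate_hc_scenario(("a", "b"), graded_scenario, params, rng)
            assert res.transcript.consensus_after_attempt1
            assert res.transcript.attempt2 is None

    def test_transcript_internal_consistency_enforced(self):
        with pytest.raises(ValueError):
            TeamTranscript(
                team_id="t", scenario_id="s", attempt1=("a", "b"),
                consensus_after_attempt1=True, attempt2=("a", "a"),
                consensus_final=True, elapsed_seconds=10.0, limit_exceeded=False,
            )


class TestICRounds:
    @pytest.fixture
    def ic_group(self):
        return Group("IC01", Arm.IC, tuple(f"p{i}" for i in range(8)))

    def test_null_dynamics_rounds_are_iid_baseline(self, ic_group, graded_scenario, rng):
        params = uniform_params([graded_scenario], evidence_attraction=0.0, conformity=0.0)
        counts = {1: {}, 2: {}, 3: {}}
        for _ in range(300):
            rounds = simulate_ic_rounds(ic_group, graded_scenario, params, rng)
            for rnd, answers in rounds.items():
                for o in answers.values():
                    counts[rnd][o] = counts[rnd].get(o, 0) + 1
        for rnd in (1, 2, 3):
            freqs = np.array([counts[rnd].get(o, 0) for o in graded_scenario.option_ids])
            props = freqs / freqs.sum()
            # uniform over 4 options, n = 2400 draws → tolerance ~5 SEs
            assert np.all(np.abs(props - 0.25) < 0.05)

    def test_full_conformity_converges_to_majority(self, ic_group, graded_scenario, rng):
        params = uniform_params([graded_scenario], evidence_attraction=0.0, conformity=1.0)
        rounds = simulate_ic_rounds(ic_group, graded_scenario, params, rng)
        assert len(set(rounds[3].values())) == 1

    def test_evidence_pull_raises_score_across_rounds(self, ic_group, graded_scenario, rng):
        from consensim.scoring import group_evidence_score

        params = uniform_params([graded_scenario], evidence_attraction=0.5, conformity=0.3)
        deltas = []
        for _ in range(200):
            rounds = simulate_ic_rounds(ic_group, graded_scenario, params, rng)
            s1 = group_evidence_score(list(rounds[1].values()), graded_scenario).value
            s3 = group_evidence_score(list(rounds[3].values()), graded_scenario).value
            deltas.append(s3 - s1)
        assert np.mean(deltas) > 0.1


class TestRankTeams:
    def _t(self, team, scen, consensus, elapsed, exceeded=False):
        return TeamTranscript(
            team_id=team, scenario_id=scen, attempt1=("a", "a") if consensus else ("a", "b"),
            consensus_after_attempt1=consensus,
            attempt2=None if consensus else ("a", "b"),
            consensus_final=consensus, elapsed_seconds=elapsed, limit_exceeded=exceeded,
        )

    def test_consensus_count_dominates_time(self):
        ts = [self._t("A", s, True, 75.0) for s in "wxyz"]
        ts += [self._t("B", s, True, 50.0) for s in "wxy"] + [self._t("B", "z", False, 50.0)]
        ranking = rank_teams(ts)
        assert [e.team_id for e in ranking] == ["A", "B"]
        assert ranking[0].consensus_count == 4

    def test_time_breaks_equal_counts(self):
        ts = [self._t("A", "w", True, 300.0), self._t("B", "w", True, 200.0)]
        assert [e.team_id for e in rank_teams(ts)] == ["B", "A"]

    def test_exceed_count_ranks_before_time(self):
        ts = [self._t("A", "w", True, 100.0, exceeded=True), self._t("B", "w", True, 300.0)]
        assert [e.team_id for e in rank_teams(ts)] == ["B", "A"]

    def test_exact_tie_falls_back_to_team_id(self):
        ts = [self._t("B", "w", True, 100.0), self._t("A", "w", True, 100.0)]
        assert [e.team_id for e in rank_teams(ts)] == ["A", "B"]

    def test_missing_transcript_rejected(self):
        ts = [self._t("A", "w", True, 10.0), self._t("A", "x", True, 10.0),
              self._t("B", "w", True, 10.0)]
        with pytest.raises(ValueError, match="missing"):
            rank_teams(ts)


class TestSimulateTrial:
    def test_study_shaped_record_count(self, design, behavior):
        trial = simulate_trial(design, behavior, seed=11)
        assert len(trial.table.frame) == 120 * 4 * 3
        assert validate_trial(trial.table).is_empty
        assert len(trial.rankings) == 8
        # 8 groups × 4 teams × 4 scenarios transcripts at minimum
        assert len(trial.transcripts) == 8 * 4 * 4

    def test_same_seed_reproduces_everything(self, design, behavior):
        t1 = simulate_trial(design, behavior, seed=99)
        t2 = simulate_trial(design, behavior, seed=99)
        assert t1.table == t2.table
        assert t1.transcripts == t2.transcripts
        assert t1.rankings == t2.rankings
        t3 = simulate_trial(design, behavior, seed=100)
        assert t3.table != t1.table

    def test_consensus_implies_equal_round2_records(self, design, behavior):
        trial = simulate_trial(design, behavior, seed=13)
        frame = trial.table.frame
        members = trial.team_members
        r2 = frame[frame["round"] == 2].set_index(["participant_id", "scenario_id"])["option_id"]
        for t in trial.transcripts:
            if t.consensus_final:
                a, b = members[t.team_id]
                assert r2[(a, t.scenario_id)] == r2[(b, t.scenario_id)]

    def test_transcripts_frame_is_long_format(self, design, behavior):
        trial = simulate_trial(design, behavior, seed=13)
        tf = transcripts_frame(trial.transcripts, teams=trial.team_members)
        assert list(tf.columns) == [
            "team_id", "scenario_id", "attempt", "participant_id", "option_id",
            "consensus", "elapsed_seconds", "limit_exceeded",
        ]
        # two rows per attempt, at least one attempt per team × scenario
        assert len(tf) >= 2 * 8 * 4 * 4
        assert set(tf["attempt"]) <= {1, 2}

    def test_null_model_centers_kappa_change_on_zero(self, scenarios):
        # ε = γ = 0: round 3 is a fresh draw, so agreement change averages 0
        params = uniform_params(scenarios, evidence_attraction=0.0, conformity=0.0)
        design = TrialDesign(scenarios=scenarios, n_hc_groups=2, n_ic_groups=2)
        deltas = []
        for seed in range(120):
            trial = simulate_trial(design, params, seed=seed)
            series = compute_outcome_series(trial.table)
            wide = series.pivot_table(
                index=["group_id", "scenario_id"], columns="round", values="kappa"
            )
            deltas.extend((wide[3] - wide[1]).tolist())
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 4 * se + 1e-9
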