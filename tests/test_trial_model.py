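import pandas as pd
import pytest

from consensim.trial_model import (
    ANSWER_COLUMNS,
    AnswerTable,
    Arm,
    EvidenceMark,
    Direction,
    Grade,
    Group,
    Scenario,
    TrialFormatError,
    TrialValidationError,
    load_answers,
    load_scenarios,
    validate_trial,
    write_answers,
    write_scenarios,
)
from tests.conftest import make_option

SCENARIO_YAML = """\
scenarios:
  - scenario_id: s1
    topic: imaging
    options:
      - {option_id: a, label: "no imaging", grade: high, direction: pro}
      - {option_id: b, label: "x-ray", grade: low, direction: contra}
  - scenario_id: s2
    topic: therapy
    options:
      - {option_id: a, label: "stay active", grade: high, direction: pro}
      - {option_id: b, label: "bed rest", grade: moderate, direction: contra}
  - scenario_id: s3
    topic: drugs
    options:
      - {option_id: a, label: "nsaid", grade: moderate, direction: pro}
      - {option_id: b, label: "opioid", grade: very_low, direction: contra}
  - scenario_id: s4
    topic: sick leave
    options:
      - {option_id: a, label: "none", grade: absent, direction: none}
      - {option_id: b, label: "a week", grade: absent, direction: none}
"""


class TestEvidenceMark:
    def test_absent_iff_direction_none(self):
        with pytest.raises(TrialValidationError):
            EvidenceMark(Grade.ABSENT, Direction.PRO)
        with pytest.raises(TrialValidationError):
            EvidenceMark(Grade.HIGH, Direction.NONE)
        assert EvidenceMark(Grade.ABSENT, Direction.NONE).grade is Grade.ABSENT


class TestLoadScenarios:
    def test_study_shaped_file(self, tmp_path):
        p = tmp_path / "scenarios.yaml"
        p.write_text(SCENARIO_YAML)
        scens = load_scenarios(p)
        assert [s.scenario_id for s in scens] == ["s1", "s2", "s3", "s4"]
        assert [s.has_evidence for s in scens] == [True, True, True, False]

    def test_single_option_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(
            "scenarios:\n- scenario_id: s\n  topic: t\n  options:\n"
            "  - {option_id: a, label: only, grade: high, direction: pro}\n"
        )
        with pytest.raises(TrialValidationError, match="≥2 options"):
            load_scenarios(p)

    def test_all_absent_means_no_evidence(self, ungraded_scenario):
        assert ungraded_scenario.has_evidence is False

    def test_duplicate_option_id_rejected(self):
        with pytest.raises(TrialValidationError, match="duplicate option_id"):
            Scenario(
                "dup", "t",
                (make_option("a", "high", "pro"), make_option("a", "low", "pro")),
            )

    def test_unparseable_yaml_names_line(self, tmp_path):
        p = tmp_path / "broken.yaml"
        p.write_text("scenarios:\n  - scenario_id: s\n   bad_indent: {x\n")
        with pytest.raises(TrialFormatError, match="line"):
            load_scenarios(p)

    def test_roundtrip(self, tmp_path, scenarios):
        p = tmp_path / "rt.yaml"
        write_scenarios(scenarios, p)
        assert load_scenarios(p) == scenarios


def _complete_frame(scenarios, group):
    rows = [
        (pid, group.group_id, group.arm.value, s.scenario_id, rnd, s.option_ids[0])
        for pid in group.participant_ids
        for s in scenarios
        for rnd in (1, 2, 3)
    ]
    return pd.DataFrame(rows, columns=ANSWER_COLUMNS)


@pytest.fixture
def one_group():
    members = tuple(f"p{i}" for i in range(8))
    teams = tuple((members[i], members[i + 1]) for i in range(0, 8, 2))
    return Group("G1", Arm.HC, members, teams)


class TestLoadAnswers:
    def test_well_formed_96_rows(self, tmp_path, scenarios, one_group):
        p = tmp_path / "answers.csv"
        _complete_frame(scenarios, one_group).to_csv(p, index=False)
        table = load_answers(p, scenarios, (one_group,))
        assert len(table.frame) == 8 * 4 * 3
        assert len(table.records) == 96

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda f: f.assign(round=[4] + [1] * (len(f) - 1)), "round"),
            (lambda f: f.assign(option_id=["nope"] + list(f.option_id[1:])), "option_id"),
            (lambda f: pd.concat([f, f.iloc[[0]]]), "duplicate"),
            (lambda f: f.assign(scenario_id=["ghost"] + list(f.scenario_id[1:])), "scenario"),
        ],
    )
    def test_invalid_rows_rejected(self, tmp_path, scenarios, one_group, mutate, match):
        frame = mutate(_complete_frame(scenarios, one_group))
        p = tmp_path / "bad.csv"
        frame.to_csv(p, index=False)
        with pytest.raises(TrialValidationError, match=match):
            load_answers(p, scenarios, (one_group,))

    def test_roundtrip_preserves_table(self, tmp_path, scenarios, one_group):
        table = AnswerTable(_complete_frame(scenarios, one_group), scenarios, (one_group,))
        p = tmp_path / "rt.csv"
        write_answers(table, p)
        assert load_answers(p, scenarios, (one_group,)) == table


class TestValidateTrial:
    def test_complete_table_is_clean(self, scenarios, one_group):
        table = AnswerTable(_complete_frame(scenarios, one_group), scenarios, (one_group,))
        assert validate_trial(table).is_empty

    def test_short_group_flagged(self, scenarios):
        members = tuple(f"p{i}" for i in range(7))
        g = Group("G7", Arm.IC, members)
        frame = pd.DataFrame(
            [
                (pid, "G7", "IC", s.scenario_id, rnd, s.option_ids[0])
                for pid in members for s in scenarios for rnd in (1, 2, 3)
            ],
            columns=ANSWER_COLUMNS,
        )
        report = validate_trial(AnswerTable(frame, scenarios, (g,)))
        assert any(f.code == "group_size" for f in report.findings)

    def test_double_teamed_participant_flagged(self, scenarios, one_group):
        bad_teams = tuple(
            (one_group.participant_ids[0], one_group.participant_ids[i]) for i in (1, 2, 3, 4)
        )
        g = Group("G1", Arm.HC, one_group.participant_ids, bad_teams)
        table = AnswerTable(_complete_frame(scenarios, g), scenarios, (g,))
        report = validate_trial(table)
        assert any(f.code == "team_partition" for f in report.findings)

    def test_missing_cell_flagged_not_imputed(self, scenarios, one_group):
        frame = _complete_frame(scenarios, one_group).iloc[1:]
        table = AnswerTable(frame, scenarios, (one_group,))
        report = validate_trial(table)
        assert any(f.code == "missing_cell" for f in report.findings)
        assert len(table.frame) == 95
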