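"""Domain model for multi-round consensus trials.

A trial presents clinical scenarios (multiple-choice questions whose options
carry a graded level of evidence, pro or contra) to groups of participants who
answer at three measurement rounds: before, during, and after the consensus
process.  This module defines the value types, the on-disk formats, and the
referential validation every downstream computation relies on.

Formats
-------
* Scenarios: a YAML document with a top-level ``scenarios`` list; each entry
  has ``scenario_id``, ``topic`` and an ``options`` list of
  ``{option_id, label, grade, direction}`` mappings.
* Answers: a UTF-8 CSV with header
  ``participant_id,group_id,arm,scenario_id,round,option_id``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Grade",
    "Direction",
    "Arm",
    "EvidenceMark",
    "AnswerOption",
    "Scenario",
    "Group",
    "AnswerRecord",
    "AnswerTable",
    "Finding",
    "ValidationReport",
    "TrialFormatError",
    "TrialValidationError",
    "load_scenarios",
    "parse_scenarios",
    "write_scenarios",
    "load_answers",
    "write_answers",
    "validate_trial",
]

ANSWER_COLUMNS = ["participant_id", "group_id", "arm", "scenario_id", "round", "option_id"]


class TrialFormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


class TrialValidationError(ValueError):
    """Raised when parsed input violates a structural invariant."""


class Grade(str, enum.Enum):
    """GRADE-style quality-of-evidence level attached to an answer option."""

    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"
    VERY_LOW = "very_low"
    ABSENT = "absent"


class Direction(str, enum.Enum):
    """Whether the evidence supports (pro) or opposes (contra) the option."""

    PRO = "pro"
    CONTRA = "contra"
    NONE = "none"


class Arm(str, enum.Enum):
    """Trial arm: game-based human computation (HC) or informal consensus (IC)."""

    HC = "HC"
    IC = "IC"


@dataclass(frozen=True)
class EvidenceMark:
    """Evidence annotation of one answer option.

    ``grade`` is absent if and only if ``direction`` is none: an option either
    carries graded, directed evidence or carries no evidence at all.
    """

    grade: Grade
    direction: Direction

    def __post_init__(self) -> None:
        grade = Grade(self.grade)
        direction = Direction(self.direction)
        object.__setattr__(self, "grade", grade)
        object.__setattr__(self, "direction", direction)
        if (grade is Grade.ABSENT) != (direction is Direction.NONE):
            raise TrialValidationError(
                f"inconsistent evidence mark: grade={grade.value}, direction={direction.value} "
                "(grade 'absent' requires direction 'none' and vice versa)"
            )


@dataclass(frozen=True)
class AnswerOption:
    option_id: str
    label: str
    evidence: EvidenceMark


@dataclass(frozen=True)
class Scenario:
    """A multiple-choice clinical question.

    ``has_evidence`` is derived: true iff at least one option carries a grade
    other than absent.  It is never read from a file.
    """

    scenario_id: str
    topic: str
    options: tuple[AnswerOption, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "options", tuple(self.options))
        if len(self.options) < 2:
            raise TrialValidationError(
                f"scenario {self.scenario_id!r} needs ≥2 options, got {len(self.options)}"
            )
        ids = [o.option_id for o in self.options]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise TrialValidationError(
                f"scenario {self.scenario_id!r} has duplicate option_id(s): {sorted(dupes)}"
            )

    @property
    def has_evidence(self) -> bool:
        return any(o.evidence.grade is not Grade.ABSENT for o in self.options)

    @property
    def option_ids(self) -> tuple[str, ...]:
        return tuple(o.option_id for o in self.options)

    def option(self, option_id: str) -> AnswerOption:
        for o in self.options:
            if o.option_id == option_id:
                return o
        raise KeyError(f"scenario {self.scenario_id!r} has no option {option_id!r}")


@dataclass(frozen=True)
class Group:
    """One consensus group of eight participants.

    HC groups carry four disjoint teams of two (the game is played pairwise);
    IC groups have no team structure at round 1.
    """

    group_id: str
    arm: Arm
    participant_ids: tuple[str, ...]
    teams: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "arm", Arm(self.arm))
        object.__setattr__(self, "participant_ids", tuple(self.participant_ids))
        object.__setattr__(self, "teams", tuple(tuple(t) for t in self.teams))


@dataclass(frozen=True)
class AnswerRecord:
    participant_id: str
    group_id: str
    arm: Arm
    scenario_id: str
    round: int
    option_id: str


@dataclass(frozen=True)
class Finding:
    """One validation finding: a machine-readable code plus human context."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    def add(self, code: str, message: str) -> None:
        self.findings.append(Finding(code, message))

    @property
    def is_empty(self) -> bool:
        return not self.findings

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"code": f.code, "message": f.message} for f in self.findings],
            columns=["code", "message"],
        )

    def __str__(self) -> str:
        if self.is_empty:
            return "OK: no findings"
        return "\n".join(str(f) for f in self.findings)


@dataclass
class AnswerTable:
    """Long-format answer data: one row per (participant, scenario, round).

    The canonical in-memory container is a :class:`pandas.DataFrame` with the
    columns of :data:`ANSWER_COLUMNS`; ``records`` materialises it as typed
    objects when needed.
    """

    frame: pd.DataFrame
    scenarios: tuple[Scenario, ...]
    groups: tuple[Group, ...]

    def __post_init__(self) -> None:
        missing = [c for c in ANSWER_COLUMNS if c not in self.frame.columns]
        if missing:
            raise TrialValidationError(f"answer table missing column(s): {missing}")
        self.frame = self.frame[ANSWER_COLUMNS].reset_index(drop=True)
        self.frame["round"] = self.frame["round"].astype(int)
        self.scenarios = tuple(self.scenarios)
        self.groups = tuple(self.groups)

    @property
    def records(self) -> list[AnswerRecord]:
        return [
            AnswerRecord(
                participant_id=r.participant_id,
                group_id=r.group_id,
                arm=Arm(r.arm),
                scenario_id=r.scenario_id,
                round=int(r.round),
                option_id=r.option_id,
            )
            for r in self.frame.itertuples(index=False)
        ]

    def scenario(self, scenario_id: str) -> Scenario:
        for s in self.scenarios:
            if s.scenario_id == scenario_id:
                return s
        raise KeyError(f"unknown scenario {scenario_id!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnswerTable):
            return NotImplemented
        key = ["participant_id", "scenario_id", "round"]
        a = self.frame.sort_values(key).reset_index(drop=True)
        b = other.frame.sort_values(key).reset_index(drop=True)
        return a.equals(b) and self.scenarios == other.scenarios and self.groups == other.groups


# ---------------------------------------------------------------------------
# Scenario I/O


def _parse_option(raw: Mapping, scenario_id: str) -> AnswerOption:
    try:
        grade = Grade(str(raw.get("grade", "absent")))
        direction = Direction(str(raw.get("direction", "none")))
    except ValueError as exc:
        raise TrialFormatError(f"scenario {scenario_id!r}: {exc}") from exc
    try:
        return AnswerOption(
            option_id=str(raw["option_id"]),
            label=str(raw.get("label", "")),
            evidence=EvidenceMark(grade=grade, direction=direction),
        )
    except KeyError as exc:
        raise TrialFormatError(f"scenario {scenario_id!r}: option missing field {exc}") from exc


def parse_scenarios(doc: Mapping) -> tuple[Scenario, ...]:
    """Build scenarios from an already-parsed mapping (see module docstring)."""
    if not isinstance(doc, Mapping) or "scenarios" not in doc:
        raise TrialFormatError("scenario document must contain a top-level 'scenarios' list")
    out = []
    for raw in doc["scenarios"]:
        sid = str(raw.get("scenario_id", "<missing scenario_id>"))
        options = [_parse_option(o, sid) for o in raw.get("options", [])]
        out.append(Scenario(scenario_id=sid, topic=str(raw.get("topic", "")), options=options))
    ids = [s.scenario_id for s in out]
    if len(set(ids)) != len(ids):
        raise TrialValidationError(f"duplicate scenario_id(s) in document: {ids}")
    return tuple(out)


def load_scenarios(path: str | Path) -> tuple[Scenario, ...]:
    """Load and validate scenarios from a YAML file.

    ``has_evidence`` on each scenario is derived from the parsed option grades.
    Raises :class:`TrialFormatError` on unparseable input (naming the line
    where YAML reports it) and :class:`TrialValidationError` on invariant
    violations such as duplicate option ids or fewer than two options.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise TrialFormatError(f"cannot parse {path}{where}: {exc}") from exc
    if doc is None:
        raise TrialFormatError(f"{path} is empty")
    return parse_scenarios(doc)


def write_scenarios(scenarios: Iterable[Scenario], path: str | Path) -> None:
    doc = {
        "scenarios": [
            {
                "scenario_id": s.scenario_id,
                "topic": s.topic,
                "options": [
                    {
                        "option_id": o.option_id,
                        "label": o.label,
                        "grade": o.evidence.grade.value,
                        "direction": o.evidence.direction.value,
                    }
                    for o in s.options
                ],
            }
            for s in scenarios
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# Answer I/O


def _check_answer_frame(
    frame: pd.DataFrame, scenarios: Sequence[Scenario], groups: Sequence[Group]
) -> None:
    """Referential checks; raises TrialValidationError listing offending rows."""
    problems = []
    scen_by_id = {s.scenario_id: s for s in scenarios}
    group_ids = {g.group_id for g in groups}
    rounds = pd.to_numeric(frame["round"], errors="coerce")
    bad_round = frame.index[~rounds.isin([1, 2, 3])]
    for i in bad_round:
        problems.append(f"row {i}: round={frame.at[i, 'round']!r} not in {{1,2,3}}")
    for i, (sid, oid, gid) in enumerate(
        zip(frame["scenario_id"], frame["option_id"], frame["group_id"])
    ):
        scen = scen_by_id.get(sid)
        if scen is None:
            problems.append(f"row {i}: unknown scenario_id {sid!r}")
        elif oid not in scen.option_ids:
            problems.append(f"row {i}: option_id {oid!r} not in scenario {sid!r}")
        if groups and gid not in group_ids:
            problems.append(f"row {i}: unknown group_id {gid!r}")
    key = ["participant_id", "scenario_id", "round"]
    dup = frame[frame.duplicated(subset=key, keep=False)]
    for k, sub in dup.groupby(key):
        problems.append(f"duplicate records for (participant, scenario, round)={k}: rows {list(sub.index)}")
    if problems:
        raise TrialValidationError("invalid answer table:\n" + "\n".join(problems))


def load_answers(
    path: str | Path, scenarios: Sequence[Scenario], groups: Sequence[Group] = ()
) -> AnswerTable:
    """Load an answer CSV and check every referential invariant.

    Row order is irrelevant.  Unknown option or scenario ids, rounds outside
    {1,2,3} and duplicate (participant, scenario, round) keys raise
    :class:`TrialValidationError` listing the offending rows.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise TrialFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in ANSWER_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing column(s) {missing}")
    _check_answer_frame(frame, scenarios, groups)
    frame["round"] = frame["round"].astype(int)
    return AnswerTable(frame=frame, scenarios=tuple(scenarios), groups=tuple(groups))


def write_answers(table: AnswerTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trial-level validation


def validate_trial(table: AnswerTable, group_size: int = 8) -> ValidationReport:
    """Structural audit of a full trial's answer data.

    Reports missing (participant, scenario, round) cells, group-size
    violations, and HC team partitions that do not split the group into
    disjoint pairs.  An empty report means the table is fully consistent.
    Missing cells are reported, never imputed: analyses downstream require
    complete cells, and real panels have shifting denominators that an
    analyst must see rather than have papered over.
    """
    report = ValidationReport()
    frame = table.frame
    for g in table.groups:
        if len(g.participant_ids) != group_size:
            report.add(
                "group_size",
                f"group {g.group_id!r}: size {len(g.participant_ids)} ≠ {group_size}",
            )
        if g.arm is Arm.HC:
            teamed = [p for t in g.teams for p in t]
            if sorted(teamed) != sorted(g.participant_ids) or any(len(t) != 2 for t in g.teams):
                report.add(
                    "team_partition",
                    f"group {g.group_id!r}: teams {g.teams} do not partition "
                    f"participants into disjoint pairs",
                )
    seen = {
        (r.participant_id, r.scenario_id, int(r.round))
        for r in frame.itertuples(index=False)
    }
    for g in table.groups:
        for p in g.participant_ids:
            for s in table.scenarios:
                for rnd in (1, 2, 3):
                    if (p, s.scenario_id, rnd) not in seen:
                        report.add(
                            "missing_cell",
                            f"no answer for participant {p!r}, scenario "
                            f"{s.scenario_id!r}, round {rnd}",
                        )
    return report
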