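"""Group-level outcome statistics for consensus trials.

Two outcomes are computed per group × scenario × round:

* **Evidence score** — how concordant a group's answers are with clinical
  evidence.  Each evidence level earns points (high 4, moderate 3, low 2,
  very low 1; evidence *against* an option earns the same points with the
  opposite sign).  Points of the chosen options are summed over the group's
  members and divided by the highest score the group could possibly attain
  (members × maximum option points).  A score of 1 means every member picked
  the best-evidenced option; the score always lies in [−1, 1].

* **Agreement kappa** — chance-corrected within-group agreement for a single
  item rated by several raters.  Observed agreement is the fraction of
  concordant rater pairs.  Two chance models are available: *free-marginal*
  (Pe = 1/k for k answer categories; the Brennan–Prediger/Randolph convention,
  the default here because a single item gives no stable marginals) and
  *fixed-marginal* (Fleiss-style Pe = Σ share², degenerate when everybody
  agrees).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .trial_model import AnswerTable, Direction, EvidenceMark, Grade, Scenario

__all__ = [
    "GRADE_POINTS",
    "ChanceModel",
    "EvidenceScore",
    "AgreementScore",
    "UndefinedScoreError",
    "evidence_points",
    "max_option_points",
    "group_evidence_score",
    "group_agreement",
    "compute_outcome_series",
]

GRADE_POINTS = {
    Grade.HIGH: 4,
    Grade.MODERATE: 3,
    Grade.LOW: 2,
    Grade.VERY_LOW: 1,
    Grade.ABSENT: 0,
}

ChanceModel = Literal["free_marginal", "fixed_marginal"]


class UndefinedScoreError(ValueError):
    """Raised when a score has no defined value for the given input."""


@dataclass(frozen=True)
class EvidenceScore:
    group_id: str
    scenario_id: str
    round: int
    value: float


@dataclass(frozen=True)
class AgreementScore:
    group_id: str
    scenario_id: str
    round: int
    kappa: float
    chance_model: ChanceModel


def evidence_points(mark: EvidenceMark) -> int:
    """Signed points for one evidence mark.

    high → 4, moderate → 3, low → 2, very_low → 1, absent → 0; a *contra*
    direction negates the points.
    """
    pts = GRADE_POINTS[mark.grade]
    return -pts if mark.direction is Direction.CONTRA else pts


def max_option_points(scenario: Scenario) -> int:
    """Highest (positive) points any single option of the scenario carries."""
    return max(evidence_points(o.evidence) for o in scenario.options)


def group_evidence_score(
    option_ids: Sequence[str], scenario: Scenario, *, group_id: str = "", round: int = 0
) -> EvidenceScore:
    """Normalized signed evidence score of one group at one round.

    ``option_ids`` are the chosen options of the group's members (one entry
    per member).  The score is Σ points(choice) / (n_members · max points) and
    is undefined for scenarios without evidence or whose maximum points are
    not positive.
    """
    if not scenario.has_evidence:
        raise UndefinedScoreError(
            f"evidence score undefined for evidence-free scenario {scenario.scenario_id!r}"
        )
    max_pts = max_option_points(scenario)
    if max_pts <= 0:
        raise UndefinedScoreError(
            f"scenario {scenario.scenario_id!r}: maximum option points {max_pts} ≤ 0, "
            "normalization undefined"
        )
    if len(option_ids) == 0:
        raise UndefinedScoreError("no answers supplied")
    pts = {o.option_id: evidence_points(o.evidence) for o in scenario.options}
    total = sum(pts[oid] for oid in option_ids)
    value = total / (len(option_ids) * max_pts)
    return EvidenceScore(group_id=group_id, scenario_id=scenario.scenario_id, round=round, value=value)


def group_agreement(
    option_ids: Sequence[str],
    n_categories: int,
    chance_model: ChanceModel = "free_marginal",
    *,
    group_id: str = "",
    scenario_id: str = "",
    round: int = 0,
) -> AgreementScore:
    """Single-item multirater kappa from pairwise agreement.

    Po is the fraction of the n·(n−1)/2 rater pairs that chose the same
    option.  Pe is 1/n_categories under the free-marginal chance model, or
    the sum of squared category shares under the fixed-marginal one.  The
    fixed-marginal model is degenerate (Pe = 1) when all raters agree, which
    raises :class:`UndefinedScoreError`.
    """
    n = len(option_ids)
    if n < 2:
        raise UndefinedScoreError(f"agreement needs ≥2 raters, got {n}")
    if n_categories < 2:
        raise UndefinedScoreError(f"agreement needs ≥2 categories, got {n_categories}")
    counts = pd.Series(list(option_ids)).value_counts().to_numpy(dtype=float)
    po = float((counts * (counts - 1)).sum() / (n * (n - 1)))
    if chance_model == "free_marginal":
        pe = 1.0 / n_categories
    elif chance_model == "fixed_marginal":
        shares = counts / n
        pe = float((shares**2).sum())
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown chance model {chance_model!r}")
    if pe >= 1.0:
        raise UndefinedScoreError(
            "chance agreement Pe = 1 (all mass on one category under the "
            "fixed-marginal model); kappa undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    return AgreementScore(
        group_id=group_id, scenario_id=scenario_id, round=round, kappa=kappa,
        chance_model=chance_model,
    )


def compute_outcome_series(
    table: AnswerTable, chance_model: ChanceModel = "free_marginal"
) -> pd.DataFrame:
    """Both outcomes for every group × scenario × round in an answer table.

    Returns a tidy frame with columns ``group_id, arm, scenario_id, round,
    evidence_score, kappa, chance_model``.  Evidence scores are NaN for
    scenarios without evidence (the statistic is undefined there); kappa is
    computed for every scenario.

    Values are quantized to 12 decimals so that outcomes equal up to
    floating-point roundoff are exact ties (the downstream rank tests are
    tie-sensitive) and delimited-text round-trips are lossless.
    """
    rows = []
    scen_by_id = {s.scenario_id: s for s in table.scenarios}
    for (gid, arm, sid, rnd), sub in table.frame.groupby(
        ["group_id", "arm", "scenario_id", "round"], sort=True
    ):
        scenario = scen_by_id[sid]
        choices = sub["option_id"].tolist()
        if scenario.has_evidence:
            ev = round(group_evidence_score(choices, scenario, group_id=gid, round=rnd).value, 12)
        else:
            ev = np.nan
        kappa = round(
            group_agreement(
                choices, n_categories=len(scenario.options), chance_model=chance_model,
                group_id=gid, scenario_id=sid, round=rnd,
            ).kappa,
            12,
        )
        rows.append(
            {
                "group_id": gid,
                "arm": arm,
                "scenario_id": sid,
                "round": int(rnd),
                "evidence_score": ev,
                "kappa": kappa,
                "chance_model": chance_model,
            }
        )
    return pd.DataFrame(rows)
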