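"""Quantification of coded group-discussion transcripts.

Face-to-face consensus meetings are transcribed and every communicative
function within an utterance — a *dialogue act* — is assigned a theme from a
declared coding scheme by human analysts.  This module turns those coded
acts into counts and integer percentages per theme, measures two-coder
reliability with Cohen's kappa, and summarizes discussion times.  It does no
NLP: inputs are already-coded acts, as a CSV with header
``meeting_id,coder_id,act_index,theme``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SCHEME",
    "CodedAct",
    "ThemeTally",
    "load_coded_acts",
    "tally_themes",
    "theme_percentage",
    "intercoder_kappa",
    "mean_intercoder_kappa",
    "discussion_time",
    "summarize_times",
]

#: Synthetic reconstruction of a meeting coding scheme for guideline
#: discussions (the categories observable in published tallies of such
#: meetings: preference/judgment, explicit evidence use, uncertainty,
#: experience, citing other guidelines, and a remainder bucket).
DEFAULT_SCHEME = (
    "clinical_judgment_or_preference",
    "pro_evidence",
    "uncertainty",
    "own_or_other_experience",
    "reference_to_guidelines_or_literature",
    "other",
)


@dataclass(frozen=True)
class CodedAct:
    meeting_id: str
    coder_id: str
    act_index: int
    theme: str

    def __post_init__(self) -> None:
        if self.act_index < 1:
            raise ValueError(f"act_index must be ≥ 1, got {self.act_index}")


@dataclass(frozen=True)
class ThemeTally:
    """Counts and integer percentages of dialogue acts per theme."""

    scheme: tuple[str, ...]
    counts: Mapping[str, int]
    total: int
    percents: Mapping[str, int]

    def to_frame(self) -> pd.DataFrame:
        """Long, bar-chart-ready view: one row per theme."""
        return pd.DataFrame(
            {
                "theme": list(self.scheme),
                "count": [self.counts[t] for t in self.scheme],
                "total": self.total,
                "percent": [self.percents[t] for t in self.scheme],
            }
        )


def load_coded_acts(path: str | Path, scheme: Sequence[str] = DEFAULT_SCHEME) -> list[CodedAct]:
    frame = pd.read_csv(path, dtype={"meeting_id": str, "coder_id": str, "theme": str})
    acts = [
        CodedAct(r.meeting_id, r.coder_id, int(r.act_index), r.theme)
        for r in frame.itertuples(index=False)
    ]
    _check_scheme(acts, scheme)
    keys = [(a.meeting_id, a.coder_id, a.act_index) for a in acts]
    if len(set(keys)) != len(keys):
        dupes = {k for k in keys if keys.count(k) > 1}
        raise ValueError(f"duplicate (meeting, coder, act_index) keys: {sorted(dupes)}")
    return acts


def _check_scheme(acts: Sequence[CodedAct], scheme: Sequence[str]) -> None:
    known = set(scheme)
    for a in acts:
        if a.theme not in known:
            raise ValueError(
                f"act (meeting={a.meeting_id!r}, coder={a.coder_id!r}, "
                f"index={a.act_index}) has unknown theme {a.theme!r}"
            )


def theme_percentage(count: int, total: int) -> int:
    """Integer percentage with half-up rounding, as printed in reports.

    E.g. 177/369 → 48, 23/369 → 6, 5/369 → 1.
    """
    if total < 1:
        raise ValueError("total must be ≥ 1")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    return int(math.floor(100.0 * count / total + 0.5))


def tally_themes(acts: Sequence[CodedAct], scheme: Sequence[str] = DEFAULT_SCHEME) -> ThemeTally:
    """Count acts per theme over the full scheme (zeros for unused codes)."""
    if not acts:
        raise ValueError("empty tally: no coded acts supplied")
    _check_scheme(acts, scheme)
    counts = {t: 0 for t in scheme}
    for a in acts:
        counts[a.theme] += 1
    total = len(acts)
    percents = {t: theme_percentage(c, total) for t, c in counts.items()}
    return ThemeTally(scheme=tuple(scheme), counts=counts, total=total, percents=percents)


def intercoder_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Cohen's kappa between two coders' labels of the same acts.

    Po is the fraction of acts labelled identically; Pe is the product-of-
    marginals chance agreement Σ_c p_a(c)·p_b(c).  When both coders are
    constant *and* identical, Pe = 1 and kappa is reported as 1 by
    convention (perfect, if uninformative, agreement).
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b) or not a:
        raise ValueError("label vectors must be non-empty and of equal length")
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    cats = sorted(set(a) | set(b))
    pa = np.array([a.count(c) for c in cats], dtype=float) / n
    pb = np.array([b.count(c) for c in cats], dtype=float) / n
    pe = float(pa @ pb)
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def mean_intercoder_kappa(
    acts_a: Sequence[CodedAct], acts_b: Sequence[CodedAct]
) -> float:
    """Unweighted mean of per-meeting Cohen's kappas between two coders.

    Acts are aligned by (meeting_id, act_index); both coders must have coded
    the same acts of every shared meeting.
    """
    by_meeting_a: dict[str, dict[int, str]] = {}
    for act in acts_a:
        by_meeting_a.setdefault(act.meeting_id, {})[act.act_index] = act.theme
    by_meeting_b: dict[str, dict[int, str]] = {}
    for act in acts_b:
        by_meeting_b.setdefault(act.meeting_id, {})[act.act_index] = act.theme
    meetings = sorted(set(by_meeting_a) & set(by_meeting_b))
    if not meetings:
        raise ValueError("coders share no meetings")
    kappas = []
    for m in meetings:
        idx_a, idx_b = by_meeting_a[m], by_meeting_b[m]
        if set(idx_a) != set(idx_b):
            raise ValueError(f"meeting {m!r}: coders coded different act indices")
        order = sorted(idx_a)
        kappas.append(intercoder_kappa([idx_a[i] for i in order], [idx_b[i] for i in order]))
    return float(np.mean(kappas))


def discussion_time(start: datetime, end: datetime) -> float:
    """Elapsed seconds between the start and end of decision-making activity."""
    if end < start:
        raise ValueError(f"end {end} precedes start {start}")
    return (end - start).total_seconds()


def summarize_times(durations: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n−1) of a set of durations, in their own units."""
    x = np.asarray(durations, dtype=float)
    if x.size < 2:
        raise ValueError("need ≥ 2 durations to summarize")
    return float(x.mean()), float(x.std(ddof=1))
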