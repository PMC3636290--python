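"""Inferential statistics for group-level consensus outcomes.

The analysis treats each group's outcome (evidence score or agreement kappa)
as one observation, so sample sizes are tiny — typically 8 vs 7 groups.
Everything here is therefore exact by default: the Wilcoxon signed-rank test
enumerates the full sign-flip distribution and the Mann–Whitney U test the
full label-permutation distribution, switching to a tie-corrected normal
approximation only above ``EXACT_N_MAX`` total observations.

Effect sizes follow the Cohen's d conventions of small consensus trials:

* within-group d: |mean(round 3) − mean(round 1)| over the pooled SD
  sqrt((s1² + s3²)/2) of the two rounds,
* between-group d: mean(HC change) − mean(IC change) over the
  (n−1)-weighted pooled SD of the two change vectors.  This is *signed* by
  default — the direction of a between-arm difference is informative —
  with ``signed=False`` restoring the absolute form.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EffectSize",
    "TestResult",
    "DegenerateDataError",
    "EXACT_N_MAX",
    "within_group_d",
    "between_group_d",
    "wilcoxon_signed_rank_exact",
    "mann_whitney_u_exact",
    "bonferroni_alpha",
    "mean_ci95",
]

#: Largest total sample size for which the exact null distributions are
#: enumerated; beyond this a tie-corrected normal approximation is used.
EXACT_N_MAX = 20


class DegenerateDataError(ValueError):
    """Raised when an effect size is undefined (zero pooled spread)."""


@dataclass(frozen=True)
class EffectSize:
    scope: Literal["within", "between"]
    scenario_id: str
    outcome: Literal["evidence_score", "agreement"]
    d: float
    p_value: float
    n_hc: int
    n_ic: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    exact: bool
    no_information: bool = False


# ---------------------------------------------------------------------------
# Effect sizes


def within_group_d(values_r1: Sequence[float], values_r3: Sequence[float]) -> float:
    """Within-arm standardized change between baseline and final round."""
    r1 = np.asarray(values_r1, dtype=float)
    r3 = np.asarray(values_r3, dtype=float)
    if r1.shape != r3.shape or r1.size < 2:
        raise ValueError("need equal-length paired vectors of length ≥ 2")
    s_pooled = math.sqrt((r1.var(ddof=1) + r3.var(ddof=1)) / 2.0)
    if s_pooled == 0.0:
        raise DegenerateDataError(
            "pooled SD is zero; within-group effect size undefined "
            "(degenerate, constant outcomes)"
        )
    return abs(r3.mean() - r1.mean()) / s_pooled


def between_group_d(
    hc_changes: Sequence[float], ic_changes: Sequence[float], signed: bool = True
) -> float:
    """Standardized difference of mean round-wise change between the arms.

    The pooled SD weights each arm's Bessel-corrected variance by (n−1).
    """
    a = np.asarray(hc_changes, dtype=float)
    b = np.asarray(ic_changes, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need ≥ 2 groups per arm")
    num = a.mean() - b.mean()
    s2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    if s2 == 0.0:
        raise DegenerateDataError(
            "pooled SD is zero; between-group effect size undefined"
        )
    d = num / math.sqrt(s2)
    return d if signed else abs(d)


# ---------------------------------------------------------------------------
# Exact rank tests

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def wilcoxon_signed_rank_exact(diffs: Sequence[float]) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (Wilcoxon's original treatment) and tied absolute
    differences receive mid-ranks.  For n ≤ ``EXACT_N_MAX`` the null
    distribution of W⁺ over all 2ⁿ sign assignments is computed exactly
    (via a generating-function convolution, equivalent to enumeration);
    the two-sided p is 2·min(P(W ≤ w), P(W ≥ w)) capped at 1.  If every
    difference is zero the test carries no information and p = 1 is
    returned with ``no_information=True``.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one difference")
    d = d[d != 0.0]
    if d.size == 0:
        return TestResult(statistic=0.0, p_value=1.0, exact=True, no_information=True)
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= EXACT_N_MAX:
        # doubled ranks are integers even with mid-ranks
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        # counts[w] = number of sign assignments with doubled W+ == w
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        w2 = int(round(2 * w_plus))
        n_total = counts.sum()
        p_le = counts[: w2 + 1].sum() / n_total
        p_ge = counts[w2:].sum() / n_total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(statistic=w_plus, p_value=p, exact=True)
    res = stats.wilcoxon(d, correction=True, method="approx", alternative="two-sided")
    return TestResult(statistic=w_plus, p_value=float(res.pvalue), exact=False)


@lru_cache(maxsize=32)
def _combination_matrix(n: int, m: int) -> np.ndarray:
    """One-hot matrix of all C(n+m, n) choices of n indices out of n+m."""
    total = n + m
    combos = list(itertools.combinations(range(total), n))
    mat = np.zeros((len(combos), total), dtype=np.float64)
    for i, c in enumerate(combos):
        mat[i, list(c)] = 1.0
    return mat


def mann_whitney_u_exact(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Exact two-sided Mann–Whitney U test.

    U counts pairs where an ``a`` value exceeds a ``b`` value, plus half a
    point per tie.  For n+m ≤ ``EXACT_N_MAX`` the p-value enumerates all
    C(n+m, n) relabelings of the pooled sample, counting relabelings whose
    U is at least as far from the null mean nm/2 as the observed one; this
    handles ties exactly.  Beyond that a tie-corrected normal approximation
    is used.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    # identity: U = rank-sum(a) − n(n+1)/2, valid with mid-ranks for ties
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    mean_u = n * m / 2.0
    if n + m <= EXACT_N_MAX:
        mat = _combination_matrix(n, m)
        u_all = mat @ ranks - n * (n + 1) / 2.0
        dev = np.abs(u_all - mean_u)
        p = float(np.mean(dev >= abs(u_obs - mean_u) - 1e-9))
        return TestResult(statistic=u_obs, p_value=p, exact=True)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(statistic=u_obs, p_value=float(res.pvalue), exact=False)


# ---------------------------------------------------------------------------
# Adjustment and intervals


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level alpha/m for m outcome measures."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be ≥ 1, got {m}")
    return alpha / m


def mean_ci95(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean with t-distribution 95% CI: mean ± t₀.₉₇₅,ₙ₋₁ · s/√n."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need ≥ 2 values for a confidence interval")
    mean = float(x.mean())
    half = float(stats.t.ppf(0.975, x.size - 1) * x.std(ddof=1) / math.sqrt(x.size))
    return mean, mean - half, mean + half
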