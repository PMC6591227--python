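"""Two-sided Mann-Whitney U test with exact small-sample enumeration.

Replicate counts in noise-decoupling and adaptation experiments are tiny
(3-6 per group), where the normal approximation to the U statistic is poor
and, with ties, off-the-shelf exact routines refuse to run.  The exact
two-sided p-value is therefore computed by full enumeration of the
C(n1+n2, n1) group assignments whenever both groups have at most
``EXACT_MAX_N`` observations; this handles ties correctly.  Larger samples
fall back to the tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

EXACT_MAX_N = 8


@dataclass(frozen=True)
class RankTestResult:
    u: float
    p_value: float
    method: str  # "exact" or "asymptotic"
    n1: int
    n2: int


class RankTestInfeasibleError(ValueError):
    """Sample sizes too small to ever reach the requested significance level."""


def u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: #{(i,j): x_i > y_j} + 0.5 * #ties."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float(np.sum(x > y) + 0.5 * np.sum(x == y))


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    mid = n1 * (len(y)) / 2.0
    # ranks make U a function of which indices land in group 1
    ranks = stats.rankdata(pooled)
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mid)
    hits = 0
    total = comb(n, n1)
    idx = np.arange(n)
    for c in combinations(idx, n1):
        u = np.sum(ranks[list(c)]) - n1 * (n1 + 1) / 2.0
        if abs(u - mid) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(x, y, exact_max_n: int = EXACT_MAX_N) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both groups have <= ``exact_max_n`` observations
    (valid with ties), tie-corrected normal approximation otherwise.
    Infinite values are allowed: they participate in the ranking as extreme
    values, which is how non-recovering (infinite adaptation time) replicates
    enter the test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u = u_statistic(x, y)
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        p = _exact_two_sided_p(x, y)
        return RankTestResult(u, p, "exact", len(x), len(y))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankTestResult(u, float(res.pvalue), "asymptotic", len(x), len(y))


def min_attainable_p(n1: int, n2: int) -> float:
    """Smallest two-sided exact p for tie-free samples: 2 / C(n1+n2, n1)."""
    return 2.0 / comb(n1 + n2, n1)


def require_feasible(n1: int, n2: int, alpha: float) -> None:
    if min_attainable_p(n1, n2) > alpha:
        raise RankTestInfeasibleError(
            f"groups of size {n1} and {n2} cannot reach p < {alpha}: "
            f"minimum two-sided exact p is {min_attainable_p(n1, n2):.4g}"
        )
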