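"""Self-contained Wilcoxon–Mann–Whitney rank-sum test.

Small samples (n + m <= 20 by default) get an exact p-value by full
enumeration of all C(n+m, n) group assignments of the pooled values, which
handles ties correctly by construction.  Larger samples use the normal
approximation with tie-corrected variance and a continuity correction of
0.5.

Conventions (fixed and documented):

* U is reported for the *first* sample x: U = R_x - n(n+1)/2 with midranks
  for ties, so 0 <= U <= n*m and swapping the samples maps U -> n*m - U.
* two-sided p = min(1, 2 * min(P(U <= u), P(U >= u))) — the doubling
  convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError

EXACT_THRESHOLD = 20

_ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass
class RankTestResult:
    U: float
    n: int
    m: int
    p: float
    method: str       # "exact" | "normal"
    alternative: str


def _check(x, y, alternative: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("samples must contain only finite values")
    if alternative not in _ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")
    return x, y


def rank_sum_statistic(x, y) -> float:
    """Mann–Whitney U for sample x, with midranks for ties."""
    x, y = _check(x, y, "two-sided")
    n = len(x)
    ranks = rankdata(np.concatenate([x, y]))
    rx = ranks[:n].sum()
    return float(rx - n * (n + 1) / 2.0)


def exact_p(x, y, alternative: str = "two-sided") -> float:
    """Exact p by enumeration of all group assignments of the pooled data."""
    x, y = _check(x, y, alternative)
    n, m = len(x), len(y)
    if n + m > EXACT_THRESHOLD:
        raise ValidationError(
            f"n + m = {n + m} exceeds the exact-enumeration threshold "
            f"({EXACT_THRESHOLD}); use approx_p"
        )
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    offset = n * (n + 1) / 2.0
    u_obs = ranks[:n].sum() - offset
    total = math.comb(n + m, n)
    n_le = n_ge = 0
    eps = 1e-9
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    p_le = n_le / total
    p_ge = n_ge / total
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


def approx_p(x, y, alternative: str = "two-sided") -> float:
    """Normal approximation with tie-corrected variance, continuity correction 0.5."""
    x, y = _check(x, y, alternative)
    n, m = len(x), len(y)
    N = n + m
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    mu = n * m / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        warnings.warn("all pooled values identical; p set to 1", stacklevel=2)
        return 1.0
    sd = math.sqrt(var)

    def upper_tail(stat: float) -> float:  # P(U >= stat), continuity corrected
        z = (stat - mu - 0.5) / sd
        return float(0.5 * math.erfc(z / math.sqrt(2.0)))

    def lower_tail(stat: float) -> float:  # P(U <= stat)
        z = (stat - mu + 0.5) / sd
        return float(0.5 * math.erfc(-z / math.sqrt(2.0)))

    if alternative == "less":
        return min(1.0, lower_tail(u))
    if alternative == "greater":
        return min(1.0, upper_tail(u))
    return min(1.0, 2.0 * min(lower_tail(u), upper_tail(u)))


def wilcoxon(
    x,
    y,
    alternative: str = "two-sided",
    exact_threshold: int = EXACT_THRESHOLD,
) -> RankTestResult:
    """Rank-sum test; exact enumeration when n + m <= exact_threshold."""
    x, y = _check(x, y, alternative)
    n, m = len(x), len(y)
    u = rank_sum_statistic(x, y)
    if n + m <= exact_threshold:
        p = exact_p(x, y, alternative)
        method = "exact"
    else:
        p = approx_p(x, y, alternative)
        method = "normal"
    return RankTestResult(U=u, n=n, m=m, p=p, method=method, alternative=alternative)


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjustment, preserving input order."""
    k = len(pvalues)
    order = sorted(range(k), key=lambda i: pvalues[i])
    adjusted = [0.0] * k
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (k - rank) * pvalues[i])
        adjusted[i] = min(1.0, running)
    return adjusted
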