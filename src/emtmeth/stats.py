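"""Rank-test and tail-probability primitives.

The Mann-Whitney implementation enumerates the exact permutation null for
small samples (handling ties correctly) and falls back on the normal
approximation with tie correction and continuity correction otherwise.
The binomial upper tail is summed in log space for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

__all__ = ["MannWhitneyResult", "mann_whitney_u", "binom_sf_log", "EXACT_MAX_N"]

# exact enumeration up to C(12, 6) = 924 group assignments
EXACT_MAX_N = 12

_ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # U statistic of the first sample (pairs x > y, ties 0.5)
    p: float
    alternative: str
    method: str       # "exact" or "asymptotic"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_p(pooled: np.ndarray, n: int, u_obs: float, alternative: str) -> float:
    """Enumerate all C(n+m, n) assignments of the pooled values to the first
    group and count U statistics at least as extreme as observed."""
    N = len(pooled)
    # pairwise win matrix over pooled values; U for a subset S is
    # sum_{i in S, j not in S} w[i, j]
    w = (pooled[:, None] > pooled[None, :]).astype(float)
    w += 0.5 * ((pooled[:, None] == pooled[None, :]) & ~np.eye(N, dtype=bool))
    total = 0
    n_less = 0
    n_greater = 0
    n_two = 0
    mid = n * (N - n) / 2.0
    eps = 1e-9
    for subset in combinations(range(N), n):
        s = np.array(subset)
        mask = np.zeros(N, dtype=bool)
        mask[s] = True
        u = w[np.ix_(s, np.flatnonzero(~mask))].sum()
        total += 1
        if u <= u_obs + eps:
            n_less += 1
        if u >= u_obs - eps:
            n_greater += 1
        if abs(u - mid) >= abs(u_obs - mid) - eps:
            n_two += 1
    if alternative == "less":
        return n_less / total
    if alternative == "greater":
        return n_greater / total
    return min(1.0, n_two / total)


def mann_whitney_u(
    x,
    y,
    alternative: str = "two-sided",
    exact: bool | None = None,
) -> MannWhitneyResult:
    """Mann-Whitney U test of ``x`` against ``y``.

    ``alternative='less'`` tests for x stochastically smaller than y.
    ``exact=None`` selects exact enumeration when n + m <= 12, the
    tie-corrected normal approximation otherwise.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    u_obs = _u_statistic(x, y)
    if exact is None:
        exact = (n + m) <= EXACT_MAX_N
    if exact:
        pooled = np.concatenate([x, y])
        p = _exact_p(pooled, n, u_obs, alternative)
        return MannWhitneyResult(u_obs, p, alternative, "exact")

    # normal approximation with tie correction and continuity correction
    pooled = np.concatenate([x, y])
    N = n + m
    mu = n * m / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:
        # all values tied: the statistic is degenerate
        return MannWhitneyResult(u_obs, 1.0, alternative, "asymptotic")
    sigma = np.sqrt(sigma2)
    if alternative == "less":
        z = (u_obs - mu + 0.5) / sigma
        p = norm.cdf(z)
    elif alternative == "greater":
        z = (u_obs - mu - 0.5) / sigma
        p = norm.sf(z)
    else:
        z = (abs(u_obs - mu) - 0.5) / sigma
        p = 2.0 * norm.sf(max(z, 0.0))
    return MannWhitneyResult(u_obs, float(min(1.0, max(p, np.finfo(float).tiny))),
                             alternative, "asymptotic")


def binom_sf_log(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by exact summation of the pmf in
    log space."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    j = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
        + j * np.log(p) + (n - j) * np.log1p(-p)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))
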