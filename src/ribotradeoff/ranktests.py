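"""Rank-based nonparametric tests with tie-aware exact small-sample paths.

The genome-scale comparisons in this package pool thousands of codon times,
where the tie-corrected normal approximation is accurate, but per-gene and
null-model comparisons can involve a handful of values with heavy ties
(61 distinct codon times).  SciPy's exact methods decline ties, so the
small-sample exact paths here enumerate the permutation distribution of the
tie-adjusted (average-rank) statistic directly:

* Mann-Whitney: all C(n+m, n) assignments of the pooled values to the two
  groups, used when ``min(n, m) <= 8`` and the enumeration stays small.
* Wilcoxon signed rank: all 2^n sign assignments to the nonzero
  differences, used when ``n <= 14``.

Two-sided p-values are ``min(1, 2 * min(P(T <= t), P(T >= t)))`` under the
enumerated null.  Larger samples fall back to SciPy's tie-corrected normal
approximations.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

_EXACT_MW_MIN_N = 8
_EXACT_MW_MAX_ENUM = 50_000
_EXACT_WILCOXON_MAX_N = 14


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (e.g. all differences 0)."""


def _tail_p(null_values: np.ndarray, observed: float) -> float:
    n = len(null_values)
    lo = np.count_nonzero(null_values <= observed + 1e-9) / n
    hi = np.count_nonzero(null_values >= observed - 1e-9) / n
    return min(1.0, 2.0 * min(lo, hi))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns ``(U_x, p)``.

    ``U_x`` counts pairs (xi, yj) with xi > yj (ties half).  Exact
    tie-aware enumeration for small samples, tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("mann_whitney_u requires two non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2)

    if min(n, m) <= _EXACT_MW_MIN_N and comb(n + m, n) <= _EXACT_MW_MAX_ENUM:
        null = np.empty(comb(n + m, n))
        base = n * (n + 1) / 2
        for i, picks in enumerate(combinations(range(n + m), n)):
            null[i] = ranks[list(picks)].sum() - base
        return u_x, _tail_p(null, u_x)

    _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_x, float(p)


def wilcoxon_signed_rank(values, mu: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against median ``mu``.

    Returns ``(W_plus, p)`` where ``W_plus`` is the positive-rank sum of
    the nonzero differences ``values - mu`` (zeros dropped).  Exact
    enumeration of sign assignments for small n, normal approximation with
    tie correction otherwise.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateTestError("all values equal the hypothesised median")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= _EXACT_WILCOXON_MAX_N:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
        null = np.where(signs, ranks, 0.0).sum(axis=1)
        return w_plus, _tail_p(null, w_plus)

    _, p = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
    return w_plus, float(p)
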