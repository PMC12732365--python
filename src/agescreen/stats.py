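"""Statistical kernels for the perturbation screen.

Two primitives live here because the screen's calls depend on their exact
behaviour: the step-down Holm adjustment that defines the candidate family,
and a two-sided Mann-Whitney U test whose exact branch must remain valid
under heavy ties (perturbation probability samples are often partially or
fully tied when a model ignores a gene).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import stats as sps

__all__ = ["holm_adjust", "mann_whitney_u", "EXACT_MAX_N"]

#: Largest per-group sample size for which the exact null distribution of the
#: rank-sum statistic is enumerated; at or above this the tie-corrected normal
#: approximation is used instead.
EXACT_MAX_N = 20


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment controlling the familywise error rate.

    Sort the m raw p-values ascending, multiply the i-th smallest (1-based)
    by ``m - i + 1``, enforce monotonicity with a running maximum, cap at 1,
    and return the adjusted values in the original order.

    Parameters
    ----------
    p_values
        Raw p-values, each in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    factors = m - np.arange(m)
    adjusted_sorted = np.minimum(1.0, np.maximum.accumulate(p[order] * factors))
    adjusted = np.empty_like(p)
    adjusted[order] = adjusted_sorted
    return adjusted


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_x: float) -> float:
    """Exact two-sided p for the U statistic under the permutation null.

    Enumerates the distribution of the rank sum of a size-``len(x)`` subset
    of the pooled sample by dynamic programming over the pooled midranks
    (doubled so ties stay integral), so tied data are handled exactly. The
    two-sided p-value is the null probability of a U at least as far from
    its mean n*m/2 as the observed one.
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    # doubled midranks are integers even with ties
    ranks2 = np.round(2 * sps.rankdata(pooled)).astype(np.int64)
    total = n + m
    max_sum = int(ranks2.sum())
    # counts[k, s] = number of k-subsets of pooled with doubled-rank sum s
    counts = np.zeros((n + 1, max_sum + 1), dtype=object)
    counts[0, 0] = 1
    for r in ranks2:
        upper = min(n, total)  # bound loop; full n is fine at these sizes
        for k in range(upper - 1, -1, -1):
            row = counts[k]
            nz = np.nonzero(row)[0]
            for s in nz[::-1]:
                counts[k + 1, s + r] += row[s]
    dist = counts[n]
    # doubled U = doubled rank sum - n(n+1); deviation measured from n*m
    center2 = n * m  # doubled n*m/2
    obs_dev = abs(int(round(2 * u_x)) - center2)
    hits = 0
    total_subsets = 0
    for s in np.nonzero(dist)[0]:
        c = dist[s]
        total_subsets += c
        u2 = int(s) - n * (n + 1)
        if abs(u2 - center2) >= obs_dev:
            hits += c
    return float(Fraction(int(hits), int(total_subsets)))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``x`` versus ``y``.

    Returns ``(U, p)`` where U is the statistic for ``x``. When both sample
    sizes are below ``EXACT_MAX_N`` the p-value is exact under the
    permutation null (tie-aware enumeration); otherwise the tie-corrected
    normal approximation with continuity correction is used. A pooled sample
    with zero spread (all values identical) yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    pooled_constant = np.ptp(np.concatenate([x, y])) == 0
    if pooled_constant:
        return u_x, 1.0
    if n < EXACT_MAX_N and m < EXACT_MAX_N:
        return u_x, _exact_two_sided_p(x, y, u_x)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_x, float(res.pvalue)
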