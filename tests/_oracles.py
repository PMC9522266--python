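"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (own midrank
implementation, exhaustive enumeration, closed forms) and never calls into
reacharc, so tests compare two independent routes to the same quantity.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def midranks(values) -> np.ndarray:
    """Ranks 1..n with ties sharing the average rank (own implementation)."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=float)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def signed_rank_enumeration(diffs):
    """Exhaustive sign-flip null of the Wilcoxon signed-rank T.

    Returns (T_observed, mean_T, var_T, all_T) over all 2^n assignments of
    signs to the ranked absolute differences (zero differences must already
    be dropped).
    """
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    n = d.size
    r = midranks(np.abs(d))
    t_obs = float(r[d > 0].sum())
    ts = np.array(
        [
            float(sum(rk for rk, pos in zip(r, signs) if pos))
            for signs in itertools.product((False, True), repeat=n)
        ]
    )
    return t_obs, float(ts.mean()), float(ts.var()), ts


def mann_whitney_enumeration(x, y):
    """Exhaustive label-permutation null of the Mann-Whitney U (second group).

    Returns (U_observed, mean_U, var_U, all_U) over all C(n1+n2, n2)
    assignments of the pooled values to the second group.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n1, n2 = xv.size, yv.size
    combined = np.concatenate([xv, yv])
    r = midranks(combined)
    offset = n2 * (n2 + 1) / 2.0
    u_obs = float(r[n1:].sum() - offset)
    us = np.array(
        [
            float(r[list(idx)].sum() - offset)
            for idx in itertools.combinations(range(n1 + n2), n2)
        ]
    )
    return u_obs, float(us.mean()), float(us.var()), us


def u_count_direct(x, y) -> float:
    """U for the second group counted pair by pair (ties count one half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if yj > xi:
                u += 1.0
            elif yj == xi:
                u += 0.5
    return u


def ols_slope(y) -> float:
    """Closed-form cov(x, y)/var(x) slope on x = 0..n-1."""
    y = np.asarray(y, dtype=float)
    x = np.arange(y.size, dtype=float)
    return float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))


def exact_permutation_slope_p(y) -> float:
    """Exact two-sided shuffle p of the slope over all n! orderings."""
    y = list(y)
    n = len(y)
    obs = abs(ols_slope(y))
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(ols_slope(perm)) >= obs - 1e-12:
            count += 1
    return count / total


def cone_angle_dot(origin, p1, p2) -> float:
    """Arccos of the normalized dot product, degrees."""
    u = np.asarray(p1, dtype=float) - origin
    v = np.asarray(p2, dtype=float) - origin
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))
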