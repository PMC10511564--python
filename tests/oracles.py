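"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the T1 oracle is
an exhaustive grid search with linear subproblems, the rank-test oracles
enumerate every sign assignment / group partition, and the truncated
normal moment oracle integrates the density numerically.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.stats import kruskal as scipy_kruskal


def grid_search_ir_fit(ti, y, t1_grid=None, refine_step=0.01):
    """Brute-force three-parameter magnitude IR fit.

    For every polarity flip point k and every T1* on a 1 ms grid the
    signed model A - B exp(-TI/T1*) is linear in (A, B) and solved in
    closed form; the global best is refined on a 0.01 ms local grid.
    Returns (a, b, t1_star, rss).
    """
    ti = np.asarray(ti, dtype=float)
    y = np.asarray(y, dtype=float)
    if t1_grid is None:
        t1_grid = np.arange(50.0, 5000.0 + 0.5, 1.0)

    def best_for_grid(grid, signed):
        # design: [1, -exp(-ti/t1)] @ (A, B) = signed
        e = np.exp(-ti[None, :] / grid[:, None])  # (g, n)
        n = ti.size
        s1 = float(n)
        se = e.sum(axis=1)
        see = (e * e).sum(axis=1)
        sy = signed.sum()
        sey = (e * signed[None, :]).sum(axis=1)
        det = s1 * see - se**2
        a = (see * sy - se * sey) / det
        b = (s1 * sey - se * sy) / det  # note sign: model uses -B*e
        b = -b
        pred = a[:, None] - b[:, None] * e
        rss = ((pred - signed[None, :]) ** 2).sum(axis=1)
        bad = (a <= 0) | (b <= 0)
        rss[bad] = np.inf
        i = int(np.argmin(rss))
        return a[i], b[i], float(grid[i]), float(rss[i])

    best = None
    for k in range(ti.size + 1):
        signed = y.copy()
        signed[:k] *= -1.0
        a, b, t1s, rss = best_for_grid(t1_grid, signed)
        lo = max(t1_grid[0], t1s - 2.0)
        hi = min(t1_grid[-1], t1s + 2.0)
        fine = np.arange(lo, hi + refine_step / 2, refine_step)
        a, b, t1s, rss = best_for_grid(fine, signed)
        if best is None or rss < best[3]:
            best = (a, b, t1s, rss)
    return best


def signed_rank_exact_p(diffs) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating 2^n signs.

    Uses mid-ranks of |d| after dropping zeros, and the conventional
    two-sided definition p = min(1, 2 min(P(W+ <= w), P(W+ >= w))).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        mid = (pos + (pos + j - i)) / 2.0
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        pos += j - i + 1
        i = j + 1
    w_obs = float(ranks[d > 0].sum())
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(float(sum(r for s, r in zip(signs, ranks) if s)))
    ws = np.asarray(ws)
    lo = float(np.mean(ws <= w_obs + 1e-12))
    hi = float(np.mean(ws >= w_obs - 1e-12))
    return min(1.0, 2.0 * min(lo, hi))


def kruskal_exact_p(groups) -> float:
    """Exact Kruskal-Wallis p by enumerating every group partition.

    H is computed by scipy for each assignment of the pooled values to
    the observed group sizes; p = P(H >= H_observed).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(gs)
    sizes = [g.size for g in gs]
    h_obs = scipy_kruskal(*gs).statistic
    total = pooled.size
    count = 0
    n_assign = 0
    for assign in _partitions(tuple(range(total)), sizes):
        n_assign += 1
        parts = [pooled[list(a)] for a in assign]
        if scipy_kruskal(*parts).statistic >= h_obs - 1e-12:
            count += 1
    return count / n_assign


def _partitions(idx: tuple, sizes):
    if len(sizes) == 1:
        yield (idx,)
        return
    for first in itertools.combinations(idx, sizes[0]):
        rest = tuple(i for i in idx if i not in set(first))
        for tail in _partitions(rest, sizes[1:]):
            yield (first,) + tail


def truncnorm_mean_numeric(mu: float, sd: float, lower: float, upper: float) -> float:
    """Mean of a truncated normal by numerical integration of its density."""

    def pdf(x):
        return math.exp(-0.5 * ((x - mu) / sd) ** 2)

    z, _ = integrate.quad(pdf, lower, upper)
    m, _ = integrate.quad(lambda x: x * pdf(x), lower, upper)
    return m / z
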