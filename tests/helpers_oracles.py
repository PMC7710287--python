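"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by exhaustive enumeration or a direct loop,
deliberately avoiding the code paths (and where possible the formulas) of the
implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import rankdata


def brute_classify(pct, threshold, min_duration=2):
    """Exhaustive all-windows contraction search: (contracting, max_contraction)."""
    pct = list(pct)
    n = len(pct)
    contracting = False
    max_contraction = 0.0
    for t0 in range(n):
        for t1 in range(t0 + 1, n):
            seg = pct[t0 : t1 + 1]
            if all(seg[i + 1] <= seg[i] for i in range(len(seg) - 1)):
                drop = pct[t1] - pct[t0]
                max_contraction = min(max_contraction, drop)
                if (t1 - t0) >= min_duration and -drop > threshold:
                    contracting = True
    return contracting, max_contraction


def brute_ccf(x, y, lag):
    """Aligned-overlap Pearson coefficient at one lag, via np.corrcoef."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    pairs = [(x[t], y[t + lag]) for t in range(n) if 0 <= t + lag < n]
    xs = np.array([p[0] for p in pairs])
    ys = np.array([p[1] for p in pairs])
    return float(np.corrcoef(xs, ys)[0, 1])


def brute_wilcoxon_p(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray([v for v in diffs if v != 0], dtype=float)
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs + 1e-9)
    p_high = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_low, p_high))


def brute_mannwhitney(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)

    def u_stat(xs, ys):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in xs for yi in ys
        )

    u_obs = u_stat(a, b)
    pooled = a + b
    us = []
    for idx in itertools.combinations(range(na + nb), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(na + nb) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.asarray(us)
    u_big = max(u_obs, na * nb - u_obs)
    return u_obs, min(1.0, 2.0 * np.mean(us >= u_big - 1e-9))


def _pearson_loop(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def brute_spearman(x, y):
    """Tie-aware Spearman rho and exact permutation p by full enumeration."""
    rx = list(rankdata(x))
    ry = list(rankdata(y))
    rho = _pearson_loop(rx, ry)
    hits = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_pearson_loop(rx, list(perm))) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total
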