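"""Independent brute-force reference for the SAM computations.

Pure-Python loops over genes, samples and labelings; deliberately naive
so it shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math
import statistics

import numpy as np


def brute_d(values, idx_a, idx_b, s0):
    """d-score and pooled SE per gene, by explicit loops."""
    d, se = [], []
    n_a, n_b = len(idx_a), len(idx_b)
    for row in values:
        a = [row[j] for j in idx_a]
        b = [row[j] for j in idx_b]
        mean_a = sum(a) / n_a
        mean_b = sum(b) / n_b
        ss = sum((x - mean_a) ** 2 for x in a) + sum((x - mean_b) ** 2 for x in b)
        s = math.sqrt((1 / n_a + 1 / n_b) * ss / (n_a + n_b - 2))
        se.append(s)
        d.append((mean_a - mean_b) / (s + s0))
    return np.array(d), np.array(se)


def brute_null(values, idx_a, idx_b, s0):
    """All distinct labelings of the pooled columns; each row sorted ascending."""
    pool = list(idx_a) + list(idx_b)
    n_a = len(idx_a)
    rows = []
    for combo in itertools.combinations(range(len(pool)), n_a):
        new_a = [pool[i] for i in combo]
        new_b = [pool[i] for i in range(len(pool)) if i not in combo]
        d, _ = brute_d(values, new_a, new_b, s0)
        rows.append(sorted(d))
    return np.array(rows)


def brute_q(d_obs, null_rows, tie_tol=1e-9):
    """q-values: mean null exceedances / observed exceedances, monotonized.

    Scores within ``tie_tol`` of a threshold count as exceeding it, the
    same tie convention the implementation uses.
    """
    n_perm = len(null_rows)
    fdr = []
    for dg in d_obs:
        t = abs(dg) - tie_tol
        v = sum(
            sum(1 for x in row if abs(x) >= t) for row in null_rows
        ) / n_perm
        r = sum(1 for x in d_obs if abs(x) >= t)
        fdr.append(min(1.0, v / max(r, 1)))
    q = []
    for g, dg in enumerate(d_obs):
        q.append(min(f for f, dh in zip(fdr, d_obs) if abs(dh) <= abs(dg)))
    return np.array(q)


def brute_s0(d0, s, percentiles=range(0, 101, 5)):
    """Exhaustive scan over the candidate percentile grid.

    Mirrors the published windowed-CV rule with explicit loops: genes are
    split into equal-count windows by pooled SE, the spread of the damped
    statistic is measured per window, and the candidate minimizing the
    coefficient of variation of those spreads wins (ties to the smallest
    percentile).
    """
    d0 = np.asarray(d0, float)
    s = np.asarray(s, float)
    n = len(s)
    r = np.where(np.isfinite(d0), d0 * s, np.nan)
    order = np.argsort(s, kind="stable")
    n_windows = 100 if n >= 1000 else max(5, n // 20)
    windows = np.array_split(order, n_windows)
    best, best_cv = None, float("inf")
    for alpha in percentiles:
        cand = float(np.percentile(s, alpha))
        mads = []
        for w in windows:
            vals = [r[i] / (s[i] + cand) for i in w if np.isfinite(r[i])]
            if not vals:
                continue
            med = statistics.median(vals)
            mads.append(statistics.median(abs(x - med) for x in vals) / 0.6745)
        if not mads or statistics.mean(mads) == 0:
            continue
        cv = statistics.pstdev(mads) / statistics.mean(mads)
        if cv < best_cv - 1e-15:
            best_cv, best = cv, alpha
    return float(np.percentile(s, best)) if best is not None else float(np.percentile(s, 50))


def brute_pearson(x, y):
    """Pearson r and two-sided p via the t distribution, explicit formulas."""
    from scipy import stats as _st

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = math.sqrt(float(((x - mx) ** 2).sum()) * float(((y - my) ** 2).sum()))
    r = num / den
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * _st.t.sf(abs(t), n - 2)
    return r, p
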