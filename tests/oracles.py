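"""Independent brute-force reference implementations used only by tests.

These are deliberately written as plain loops over the defining formulas so
that they share no code path with the package implementation.
"""

import itertools

import numpy as np


def naive_dcor(a: np.ndarray, b: np.ndarray) -> float:
    """Distance correlation by explicit loops: z-score each voxel, build the
    pairwise time-point distance matrices, U-center them entrywise, then form
    the unbiased dCov/dVar and the square-root ratio (clamped at 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t = a.shape[1]

    def zscore(x):
        out = np.empty_like(x)
        for vidx in range(x.shape[0]):
            row = x[vidx]
            out[vidx] = (row - row.mean()) / row.std()
        return out

    def dist(x):
        d = np.zeros((t, t))
        for t1 in range(t):
            for t2 in range(t):
                s = 0.0
                for vidx in range(x.shape[0]):
                    s += (x[vidx, t1] - x[vidx, t2]) ** 2
                d[t1, t2] = np.sqrt(s)
        return d

    def ucenter(d):
        out = np.zeros((t, t))
        total = sum(d[p, q] for p in range(t) for q in range(t))
        for t1 in range(t):
            for t2 in range(t):
                if t1 == t2:
                    continue
                row = sum(d[t1, p] for p in range(t))
                col = sum(d[q, t2] for q in range(t))
                out[t1, t2] = (d[t1, t2] - row / (t - 2) - col / (t - 2)
                               + total / ((t - 1) * (t - 2)))
        return out

    da = ucenter(dist(zscore(a)))
    db = ucenter(dist(zscore(b)))

    def dsum(x, y):
        s = 0.0
        for t1 in range(t):
            for t2 in range(t):
                s += x[t1, t2] * y[t1, t2]
        return s / (t * (t - 3))

    dcov = dsum(da, db)
    dvar_a = dsum(da, da)
    dvar_b = dsum(db, db)
    if dcov <= 0 or dvar_a <= 0 or dvar_b <= 0:
        return 0.0
    return float(np.sqrt(dcov / np.sqrt(dvar_a * dvar_b)))


def naive_local_efficiency(n, edges, i, lengths=None) -> float:
    """Local efficiency by exhaustive enumeration of all simple paths inside
    the induced neighbor subgraph.  ``edges`` is a list of (u, v, w); edge
    lengths default to w_max / w."""
    adj = {u: {} for u in range(n)}
    wmax = max((w for _, _, w in edges), default=1.0)
    for u, v, w in edges:
        l = lengths[(u, v)] if lengths else wmax / w
        adj[u][v] = l
        adj[v][u] = l
    nbrs = sorted(adj[i])
    m = len(nbrs)
    if m < 2:
        return 0.0
    total = 0.0
    for j, k in itertools.permutations(nbrs, 2):
        best = np.inf
        # all simple paths from j to k through intermediate neighbor nodes
        others = [x for x in nbrs if x not in (j, k)]
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = [j, *mid, k]
                length = 0.0
                ok = True
                for u, v in zip(path, path[1:]):
                    if v not in adj[u]:
                        ok = False
                        break
                    length += adj[u][v]
                if ok:
                    best = min(best, length)
        if np.isfinite(best) and best > 0:
            total += 1.0 / best
    return total / (m * (m - 1))


def naive_split_plot_anova(y: np.ndarray, groups) -> dict:
    """Split-plot sums of squares by explicit summation over cells."""
    y = np.asarray(y, dtype=float)
    groups = list(groups)
    levels = sorted(set(groups))
    g = len(levels)
    n = groups.count(levels[0])
    k = y.shape[1]
    grand = y.mean()

    ss_group = 0.0
    for lv in levels:
        rows = [y[s] for s in range(y.shape[0]) if groups[s] == lv]
        ss_group += n * k * (np.mean(rows) - grand) ** 2
    ss_subj = 0.0
    for s in range(y.shape[0]):
        lv_mean = np.mean([y[r] for r in range(y.shape[0])
                           if groups[r] == groups[s]])
        ss_subj += k * (y[s].mean() - lv_mean) ** 2
    ss_cond = 0.0
    for c in range(k):
        ss_cond += g * n * (y[:, c].mean() - grand) ** 2
    ss_inter = 0.0
    for lv in levels:
        rows = np.array([y[s] for s in range(y.shape[0]) if groups[s] == lv])
        for c in range(k):
            ss_inter += n * (rows[:, c].mean() - rows.mean()
                             - y[:, c].mean() + grand) ** 2
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = ss_total - ss_group - ss_subj - ss_cond - ss_inter

    df = {"group": (g - 1, g * (n - 1)),
          "condition": (k - 1, g * (n - 1) * (k - 1)),
          "interaction": ((g - 1) * (k - 1), g * (n - 1) * (k - 1))}
    ms_subj = ss_subj / (g * (n - 1))
    ms_resid = ss_resid / (g * (n - 1) * (k - 1))
    return {
        "group": (ss_group / df["group"][0]) / ms_subj,
        "condition": (ss_cond / df["condition"][0]) / ms_resid,
        "interaction": (ss_inter / df["interaction"][0]) / ms_resid,
        "df": df,
    }


def naive_storey_q(pvals, lam=0.5):
    """Storey q-values by the defining cumulative-minimum recipe."""
    p = list(map(float, pvals))
    m = len(p)
    pi0 = min(1.0, sum(1 for x in p if x > lam) / ((1 - lam) * m))
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pi0 * m * p[i] / rank)
        q[i] = min(val, 1.0)
        prev = val
    return np.array(q)
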