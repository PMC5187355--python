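"""Definition-based dip oracle: linear-programming feasibility search.

Computes Hartigan's dip exactly for small samples with distinct values by
minimizing, over all unimodal mode configurations, the smallest band
half-width ``eps`` such that a unimodal CDF fits inside ``F +/- eps``.
A unimodal CDF is convex up to the mode, concave after, with an optional
atom (jump) at the mode; all shape and band constraints are linear in the
CDF values at the sample points, so each configuration is one LP.
Independent of the production algorithm; used only as a test oracle.
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp(x):
    x = np.sort(np.asarray(x, float))
    n = len(x)
    assert len(np.unique(x)) == n, "oracle requires distinct values"
    best = np.inf

    def solve(mode_kind, m, link_case=None):
        extra = 1 if mode_kind == "point" else 0
        nv = n + extra + 1
        ieps = nv - 1
        A_ub, b_ub = [], []

        def row():
            return np.zeros(nv)

        # band: for a continuity point i (1-based), i/n - eps <= g_i <= (i-1)/n + eps
        for i in range(1, n + 1):
            gi = i - 1
            if mode_kind == "point" and i == m:
                r = row(); r[gi] = -1; r[ieps] = -1; A_ub.append(r); b_ub.append(-i / n)
                r = row(); r[gi] = 1; r[ieps] = -1; A_ub.append(r); b_ub.append(i / n)
                r = row(); r[n] = -1; r[ieps] = -1; A_ub.append(r); b_ub.append(-(i - 1) / n)
                r = row(); r[n] = 1; r[ieps] = -1; A_ub.append(r); b_ub.append((i - 1) / n)
                r = row(); r[n] = 1; r[gi] = -1; A_ub.append(r); b_ub.append(0.0)
            else:
                r = row(); r[gi] = -1; r[ieps] = -1; A_ub.append(r); b_ub.append(-i / n)
                r = row(); r[gi] = 1; r[ieps] = -1; A_ub.append(r); b_ub.append((i - 1) / n)

        def mono(a, b):
            r = row(); r[a] = 1; r[b] = -1; A_ub.append(r); b_ub.append(0.0)

        if mode_kind == "interval":
            left = list(range(1, m + 1))
            right = list(range(m + 1, n + 1))
            lvals = [(x[i - 1], i - 1) for i in left]
            rvals = [(x[i - 1], i - 1) for i in right]
        else:
            left = list(range(1, m))
            right = list(range(m, n + 1))
            lvals = [(x[i - 1], i - 1) for i in left] + [(x[m - 1], n)]
            rvals = [(x[i - 1], i - 1) for i in right]

        for (_, a), (_, b) in zip(lvals[:-1], lvals[1:]):
            mono(a, b)
        for (_, a), (_, b) in zip(rvals[:-1], rvals[1:]):
            mono(a, b)
        if mode_kind == "interval" and left and right:
            mono(left[-1] - 1, right[0] - 1)

        # convexity of the left chain, concavity of the right chain
        for i in range(len(lvals) - 2):
            (x0, a), (x1, b), (x2, c) = lvals[i], lvals[i + 1], lvals[i + 2]
            r = row()
            r[a] = -1.0 / (x1 - x0)
            r[b] = 1.0 / (x1 - x0) + 1.0 / (x2 - x1)
            r[c] = -1.0 / (x2 - x1)
            A_ub.append(r); b_ub.append(0.0)
        if lvals:
            r = row(); r[lvals[0][1]] = -1; A_ub.append(r); b_ub.append(0.0)
        for i in range(len(rvals) - 2):
            (x0, a), (x1, b), (x2, c) = rvals[i], rvals[i + 1], rvals[i + 2]
            r = row()
            r[a] = 1.0 / (x1 - x0)
            r[b] = -1.0 / (x1 - x0) - 1.0 / (x2 - x1)
            r[c] = 1.0 / (x2 - x1)
            A_ub.append(r); b_ub.append(0.0)
        if rvals:
            r = row(); r[rvals[-1][1]] = 1; A_ub.append(r); b_ub.append(1.0)

        # interval mode: the rise across the modal gap must be achievable by
        # a convex continuation (slope >= last left slope), a jump, and a
        # concave continuation (slope >= first right slope): feasible iff
        # rise >= min(s_L, s_R) * gap, split into the two linear cases.
        if mode_kind == "interval" and 1 <= m <= n - 1:
            gap = x[m] - x[m - 1]
            if link_case == "L" and m >= 2:
                w = gap / (x[m - 1] - x[m - 2])
                r = row(); r[m - 2] = -w; r[m - 1] = 1 + w; r[m] = -1
                A_ub.append(r); b_ub.append(0.0)
            elif link_case == "R" and m + 2 <= n:
                w = gap / (x[m + 1] - x[m])
                r = row(); r[m - 1] = 1; r[m] = -1 - w; r[m + 1] = w
                A_ub.append(r); b_ub.append(0.0)

        c = np.zeros(nv); c[ieps] = 1.0
        bounds = [(None, None)] * nv
        bounds[ieps] = (0, None)
        res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds,
                      method="highs")
        return res.fun if res.success else np.inf

    for m in range(0, n + 1):
        if 1 <= m <= n - 1:
            best = min(best, solve("interval", m, "L"), solve("interval", m, "R"))
        else:
            best = min(best, solve("interval", m))
    for m in range(1, n + 1):
        best = min(best, solve("point", m))
    return best
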