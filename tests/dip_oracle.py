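"""Brute-force oracle for the dip statistic, independent of the fast algorithm.

The dip of a sample is min over unimodal CDFs G of sup |F_n - G|, where a
unimodal CDF is convex left of its mode, concave right of it, and may carry
an atom at the mode. For a discrete set of jump points the search reduces to
small linear programs: fix where the density peak sits (at a data value with
an optional atom, or strictly inside one inter-point chord), then the chord
slopes of the piecewise-linear candidate must increase up to the peak and
decrease after it, and every constraint (slope ordering, the sup-norm tube
around the ECDF, monotonicity, 0/1 limits) is linear in the G values and the
distance d. Minimizing d per peak position and taking the overall minimum
gives the exact dip. Feasible only for small n, which is the point.
"""

import numpy as np
from scipy.optimize import linprog


def _merge(values):
    v, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    n = counts.sum()
    cum = np.cumsum(counts) / n
    left = cum - counts / n  # ECDF left limits at each jump point
    return v, cum, left


def _solve(c, A_ub, b_ub, n_var):
    res = linprog(
        c,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        bounds=[(None, None)] * n_var,
        method="highs",
    )
    return res.fun if res.status == 0 else np.inf


def dip_oracle(values) -> float:
    """Exact dip by LP minimization over unimodal CDFs (atoms at the mode)."""
    v, F, Fm = _merge(values)
    m = len(v)
    if m == 1:
        return 0.0

    best = np.inf

    def tube_rows(rows, rhs, gi_col, lo, hi):
        # lo - d <= g_i <= hi + d  (d is the last variable)
        row = np.zeros(nvar); row[gi_col] = -1.0; row[-1] = -1.0
        rows.append(row); rhs.append(-lo)
        row = np.zeros(nvar); row[gi_col] = 1.0; row[-1] = -1.0
        rows.append(row); rhs.append(hi)

    # Case A: mode at data value k, atom allowed there.
    # Variables: g_0..g_{m-1}, gminus (left limit at v_k), d.
    for k in range(m):
        nvar = m + 2
        rows, rhs = [], []
        gm_col = m  # gminus
        for i in range(m):
            if i == k:
                # atom at the mode: left limit and value each get their own tube
                tube_rows(rows, rhs, gm_col, Fm[k], Fm[k])
                tube_rows(rows, rhs, k, F[k], F[k])
            else:
                tube_rows(rows, rhs, i, F[i], Fm[i])

        # point sequence for chords: left side ends at (v_k, gminus),
        # right side starts at (v_k, g_k)
        pts_left = [(v[i], i) for i in range(k)] + [(v[k], gm_col)]
        pts_right = [(v[k], k)] + [(v[i], i) for i in range(k + 1, m)]

        def add_monotone(pts):
            for (xa, ca), (xb, cb) in zip(pts[:-1], pts[1:]):
                row = np.zeros(nvar); row[ca] = 1.0; row[cb] = -1.0
                rows.append(row); rhs.append(0.0)

        def add_slope_order(pts, increasing):
            # slopes s_i = (g_{i+1}-g_i)/dx_i ordered along the sequence
            for j in range(len(pts) - 2):
                (xa, ca), (xb, cb), (xc, cc) = pts[j], pts[j + 1], pts[j + 2]
                d1, d2 = xb - xa, xc - xb
                # increasing: s_j <= s_{j+1}  ->  (g_b-g_a)*d2 - (g_c-g_b)*d1 <= 0
                row = np.zeros(nvar)
                row[ca] -= d2; row[cb] += d2
                row[cb] += d1; row[cc] -= d1
                if not increasing:
                    row = -row
                rows.append(row); rhs.append(0.0)

        add_monotone(pts_left)
        add_monotone(pts_right)
        # gminus <= g_k (atom size >= 0)
        row = np.zeros(nvar); row[gm_col] = 1.0; row[k] = -1.0
        rows.append(row); rhs.append(0.0)
        add_slope_order(pts_left, increasing=True)
        add_slope_order(pts_right, increasing=False)
        # CDF limits
        row = np.zeros(nvar); row[0 if k else gm_col] = -1.0
        rows.append(row); rhs.append(0.0)  # first value >= 0
        row = np.zeros(nvar); row[m - 1] = 1.0
        rows.append(row); rhs.append(1.0)  # last value <= 1
        # also gminus >= 0 when k == 0 handled above; ensure d >= 0
        row = np.zeros(nvar); row[-1] = -1.0
        rows.append(row); rhs.append(0.0)
        c = np.zeros(nvar); c[-1] = 1.0
        best = min(best, _solve(c, rows, rhs, nvar))

    # Case B: mode strictly inside chord k (no atom): slopes s_0..s_{m-2}
    # increase up to chord k and decrease from chord k on.
    for k in range(m - 1):
        nvar = m + 1
        rows, rhs = [], []
        for i in range(m):
            tube_rows(rows, rhs, i, F[i], Fm[i])
        for i in range(m - 1):
            row = np.zeros(nvar); row[i] = 1.0; row[i + 1] = -1.0
            rows.append(row); rhs.append(0.0)  # monotone
        dx = np.diff(v)
        for j in range(m - 2):
            row = np.zeros(nvar)
            # s_j vs s_{j+1}
            row[j] -= dx[j + 1]; row[j + 1] += dx[j + 1]
            row[j + 1] += dx[j]; row[j + 2] -= dx[j]
            if j >= k:  # decreasing side: s_j >= s_{j+1}
                row = -row
            rows.append(row); rhs.append(0.0)
        row = np.zeros(nvar); row[0] = -1.0
        rows.append(row); rhs.append(0.0)
        row = np.zeros(nvar); row[m - 1] = 1.0
        rows.append(row); rhs.append(1.0)
        row = np.zeros(nvar); row[-1] = -1.0
        rows.append(row); rhs.append(0.0)
        c = np.zeros(nvar); c[-1] = 1.0
        best = min(best, _solve(c, rows, rhs, nvar))

    return float(best)
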