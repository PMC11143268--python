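"""Brute-force LP oracle for the dip statistic.

Independent of the package implementation: models a candidate unimodal CDF
as a piecewise-linear function on a dense knot grid (all sample points plus
fillers), enumerates the mode knot (where an atom / jump is allowed), and
solves a small LP for the closest such CDF to the ECDF.  Exact whenever the
optimal unimodal CDF has its mode and corners on the grid (always true for
tie-heavy samples whose atoms are grid points); otherwise accurate to the
grid resolution.  Small n only.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _grid(x: np.ndarray, fill: int) -> np.ndarray:
    pts = [x]
    for a, b in zip(x[:-1], x[1:]):
        pts.append(np.linspace(a, b, fill + 2)[1:-1])
    lo = x[0] - (x[-1] - x[0] + 1.0)
    hi = x[-1] + (x[-1] - x[0] + 1.0)
    pts.append(np.linspace(lo, x[0], fill + 2)[:-1])
    pts.append(np.linspace(x[-1], hi, fill + 2)[1:])
    return np.unique(np.concatenate(pts))


def dip_lp(sample: np.ndarray, fill: int = 24) -> float:
    xs = np.sort(np.asarray(sample, dtype=float))
    n = xs.size
    uniq, counts = np.unique(xs, return_counts=True)
    if uniq.size == 1:
        return 1.0 / (2 * n)
    upper_u = np.cumsum(counts) / n
    lower_u = upper_u - counts / n

    g = _grid(uniq, fill)
    m = g.size
    # ECDF on the grid: F(p) and F(p-)
    Fu = np.searchsorted(uniq, g, side="right")
    Fu = np.where(Fu > 0, np.concatenate([[0.0], upper_u])[Fu], 0.0)
    Fl = np.searchsorted(uniq, g, side="left")
    Fl = np.concatenate([[0.0], upper_u])[Fl]

    best = np.inf
    for mode in range(m):
        # variables: v_0..v_{m-1} = G at grid knots, vl = G(mode-), d
        nv = m + 2
        ivl, idd = m, m + 1
        rows, rhs = [], []

        def le(coefs, b):
            r = np.zeros(nv)
            for j, c in coefs:
                r[j] += c
            rows.append(r)
            rhs.append(b)

        def leftvar(j):
            return ivl if j == mode else j

        for j in range(m):
            le([(j, 1.0), (idd, -1.0)], Fu[j])     # d >= v_j - F(p_j)
            le([(j, -1.0), (idd, -1.0)], -Fu[j])   # d >= F(p_j) - v_j
            lv = leftvar(j)
            le([(lv, 1.0), (idd, -1.0)], Fl[j])    # d >= G(p_j-) - F(p_j-)
            le([(lv, -1.0), (idd, -1.0)], -Fl[j])
        # monotone and bounded; G continuous except at the mode knot
        le([(0, 1.0), (idd, -1.0)], 0.0)           # tail below first knot: F=0
        le([(m - 1, -1.0), (idd, -1.0)], -1.0)     # tail above last knot: F=1
        le([(0, -1.0)], 0.0)
        le([(m - 1, 1.0)], 1.0)
        for j in range(1, m):
            le([(j - 1, 1.0), (leftvar(j), -1.0)], 0.0)
        le([(ivl, 1.0), (mode, -1.0)], 0.0)        # jump up at the mode
        if mode > 0:
            le([(mode - 1, 1.0), (ivl, -1.0)], 0.0)
        else:
            le([(ivl, -1.0)], 0.0)
        # convexity before the mode (the mode knot enters via its left value;
        # the slope before the first knot is free down to 0, so a convex rise
        # from 0 at -inf is always realisable)
        for j in range(2, mode + 1):
            dx1 = g[j - 1] - g[j - 2]
            dx2 = g[j] - g[j - 1]
            le([(j - 2, -dx2), (j - 1, dx2 + dx1), (leftvar(j), -dx1)], 0.0)
        # concavity after the mode (post-jump value at the mode knot)
        for j in range(mode + 2, m):
            dx1 = g[j - 1] - g[j - 2]
            dx2 = g[j] - g[j - 1]
            le([(j - 2, dx2), (j - 1, -(dx2 + dx1)), (j, dx1)], 0.0)
        # tail after last knot: concave continuation to 1 is realisable as a
        # linear ramp whenever the final slope is positive; near-degenerate
        # flat tails are resolved by the wide filler margin in the grid.

        c = np.zeros(nv)
        c[idd] = 1.0
        res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs),
                      bounds=[(None, None)] * nv, method="highs")
        if res.status == 0 and res.fun < best:
            best = res.fun
    return float(max(best, 1.0 / (2 * n)))
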