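"""Reference dip computation by direct minimization over unimodal CDFs.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF: nondecreasing, convex up to some mode, concave
after it, with at most one atom, located at the mode.  This module computes
that minimum literally.  For a fixed mode abscissa the best-fitting
constrained CDF is a linear program in the fitted values at the distinct
data points (plus the one-sided limits at the mode); the dip is the minimum
of the LP value over mode positions — every data point, and a grid with
local refinement inside every between-point gap, because an atom strictly
between two observations can be optimal.

Cost is roughly quadratic in the number of distinct values times the number
of candidate modes, so this is only meant for validating the fast
alternating GCM/LCM algorithm in :mod:`bimodalsurv._dip` on small samples.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog, minimize_scalar
from scipy.sparse import coo_matrix

__all__ = ["dip_bruteforce"]

_N_GRID = 13  # interior mode candidates per gap before refinement


def _mode_lp(xs, F, Fprev, j, mu=None):
    """Min sup-distance unimodal fit with the mode fixed.

    ``mu is None`` places the mode (and its possible atom) at the data point
    ``xs[j]``: the convex branch ends at the left limit ``a`` there, the
    concave branch starts at the fitted value ``g_j``.  Otherwise the mode
    sits at abscissa ``mu`` strictly inside the gap ``(xs[j], xs[j+1])``:
    the convex branch must keep climbing from ``g_j`` to a left limit ``a``
    at ``mu`` (chord slopes nondecreasing through the mode), the atom raises
    it to ``b``, and the concave branch runs from ``(mu, b)`` through the
    remaining points with nonincreasing chord slopes.

    Variables: g_0..g_{m-1}, a, b, d.  Between data points the ECDF is flat
    and the fit monotone, so constraints at the points, the left limits and
    the mode bound the sup distance everywhere.
    """
    m = xs.size
    point_mode = mu is None
    rows, cols, vals, rhs = [], [], [], []
    r = 0

    def add(coefs, b_):
        nonlocal r
        for c, v in coefs:
            rows.append(r)
            cols.append(c)
            vals.append(v)
        rhs.append(b_)
        r += 1

    a_col, b_col, d_col = m, m + 1, m + 2

    # ---- band constraints ------------------------------------------------
    for i in range(m):
        add([(i, -1.0), (d_col, -1.0)], -F[i])  # g_i >= F_i - d
        # left limit at x_i <= Fprev_i + d; at a point mode the left limit
        # is the convex-branch endpoint a, and g_i may jump above it
        ll = a_col if (point_mode and i == j) else i
        add([(ll, 1.0), (d_col, -1.0)], Fprev[i])
        if point_mode and i == j:
            add([(i, 1.0), (d_col, -1.0)], F[i])  # atom top within band
    if not point_mode:
        # both one-sided limits at mu sit over the flat stretch at height F_j
        add([(a_col, 1.0), (d_col, -1.0)], F[j])
        add([(b_col, 1.0), (d_col, -1.0)], F[j])

    # ---- monotonicity ----------------------------------------------------
    for i in range(m - 1):
        if point_mode and i + 1 == j:
            add([(i, 1.0), (a_col, -1.0)], 0.0)
            add([(a_col, 1.0), (i + 1, -1.0)], 0.0)
        elif (not point_mode) and i == j:
            add([(i, 1.0), (a_col, -1.0)], 0.0)
            add([(a_col, 1.0), (b_col, -1.0)], 0.0)
            add([(b_col, 1.0), (i + 1, -1.0)], 0.0)
        else:
            add([(i, 1.0), (i + 1, -1.0)], 0.0)

    # ---- shape constraints ----------------------------------------------
    # convex branch: abscissas x_0..x_{j-1}, then the mode (x_j or mu)
    cvx_x = list(xs[: j + 1]) if point_mode else list(xs[: j + 1]) + [mu]
    cvx_c = list(range(j)) + [a_col] if point_mode else list(range(j + 1)) + [a_col]
    for i in range(1, len(cvx_x) - 1):
        dx1 = cvx_x[i] - cvx_x[i - 1]
        dx2 = cvx_x[i + 1] - cvx_x[i]
        # slope_{i-1,i} <= slope_{i,i+1}
        add(
            [
                (cvx_c[i - 1], -1.0 / dx1),
                (cvx_c[i], 1.0 / dx1 + 1.0 / dx2),
                (cvx_c[i + 1], -1.0 / dx2),
            ],
            0.0,
        )
    # concave branch: the mode, then x_{j+1}..x_{m-1}
    ccv_x = [xs[j]] + list(xs[j + 1 :]) if point_mode else [mu] + list(xs[j + 1 :])
    ccv_c = ([j] if point_mode else [b_col]) + list(range(j + 1, m))
    for i in range(1, len(ccv_x) - 1):
        dx1 = ccv_x[i] - ccv_x[i - 1]
        dx2 = ccv_x[i + 1] - ccv_x[i]
        # slope_{i-1,i} >= slope_{i,i+1}
        add(
            [
                (ccv_c[i - 1], 1.0 / dx1),
                (ccv_c[i], -1.0 / dx1 - 1.0 / dx2),
                (ccv_c[i + 1], 1.0 / dx2),
            ],
            0.0,
        )

    A = coo_matrix((vals, (rows, cols)), shape=(r, m + 3))
    c = np.zeros(m + 3)
    c[d_col] = 1.0
    bounds = [(0.0, 1.0)] * (m + 2) + [(0.0, 0.5)]
    res = linprog(c, A_ub=A.tocsr(), b_ub=np.asarray(rhs), bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - d = 0.5 is always feasible
        raise RuntimeError(f"reference dip LP failed: {res.message}")
    return res.fun


def dip_bruteforce(x):
    """Dip statistic by exhaustive search over mode positions (small n only)."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    xs, counts = np.unique(x, return_counts=True)
    if xs.size == 1:
        raise ValueError("degenerate sample: all values identical")
    n = x.size
    F = np.cumsum(counts) / n
    Fprev = F - counts / n
    m = xs.size
    # every jump must be split by the fit except the one a mode atom absorbs,
    # so the second-largest jump (halved) bounds the dip from below
    lower_bound = np.partition(counts, -2)[-2] / (2.0 * n) if m >= 2 else 0.0

    best = np.inf
    # point modes, scanned from the middle outward (usually hit the bound early)
    order = np.argsort(np.abs(np.arange(m) - (m - 1) / 2.0))
    for j in order:
        best = min(best, _mode_lp(xs, F, Fprev, int(j)))
        if best <= lower_bound + 1e-12:
            return best
    # interior-gap modes: coarse grid, then Brent refinement per gap
    for j in range(m - 1):
        lo, hi = xs[j], xs[j + 1]
        grid = np.linspace(lo, hi, _N_GRID + 2)[1:-1]
        vals = [_mode_lp(xs, F, Fprev, j, mu) for mu in grid]
        if min(vals) > best + 1e-9:
            continue
        res = minimize_scalar(
            lambda mu: _mode_lp(xs, F, Fprev, j, mu),
            bounds=(lo + 1e-12 * (hi - lo), hi - 1e-12 * (hi - lo)),
            method="bounded",
            options={"xatol": 1e-10 * (hi - lo)},
        )
        best = min(best, min(vals), res.fun)
        if best <= lower_bound + 1e-12:
            return best
    return best
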