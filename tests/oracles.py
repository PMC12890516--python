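"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive - literal enumerations, grid searches
and textbook sum-of-squares decompositions - and shares no code path with the
package internals it verifies.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: sort, scale by m/rank, enforce
    monotonicity from the largest p down, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


def hypergeom_upper_tail(n_bg: int, n_term: int, n_hits: int, overlap: int) -> Fraction:
    """Exact P[X >= overlap] for a hypergeometric draw, as a Fraction."""
    total = comb(n_bg, n_hits)
    upper = min(n_term, n_hits)
    acc = sum(
        comb(n_term, k) * comb(n_bg - n_term, n_hits - k)
        for k in range(overlap, upper + 1)
    )
    return Fraction(acc, total)


def anova_oneway_f(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """One-way ANOVA F via the literal between/within sum-of-squares split."""
    values = np.asarray(values, dtype=float)
    grand = values.mean()
    ss_between = ss_within = 0.0
    levels = list(dict.fromkeys(groups))
    for g in levels:
        sub = values[np.asarray(groups) == g]
        ss_between += len(sub) * (sub.mean() - grand) ** 2
        ss_within += float(np.sum((sub - sub.mean()) ** 2))
    df_b = len(levels) - 1
    df_w = values.size - len(levels)
    f = (ss_between / df_b) / (ss_within / df_w)
    return ss_between, ss_within, f


def anova_twoway_ss(values, factor_a, factor_b) -> dict[str, float]:
    """Balanced two-way ANOVA sums of squares via the cell-means decomposition."""
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    grand = values.mean()
    a_levels = list(dict.fromkeys(factor_a))
    b_levels = list(dict.fromkeys(factor_b))
    n_cell = values.size / (len(a_levels) * len(b_levels))
    ss_a = sum(
        np.sum(factor_a == a) * (values[factor_a == a].mean() - grand) ** 2
        for a in a_levels
    )
    ss_b = sum(
        np.sum(factor_b == b) * (values[factor_b == b].mean() - grand) ** 2
        for b in b_levels
    )
    ss_cells = 0.0
    ss_error = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = values[(factor_a == a) & (factor_b == b)]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_error += float(np.sum((cell - cell.mean()) ** 2))
    return {
        "factor_a": float(ss_a),
        "factor_b": float(ss_b),
        "interaction": float(ss_cells - ss_a - ss_b),
        "error": ss_error,
        "n_cell": n_cell,
    }


def grid_search_biexp(
    t: np.ndarray,
    y: np.ndarray,
    p_grid: np.ndarray,
    tc_fast_grid: np.ndarray,
    tc_slow_grid: np.ndarray,
) -> tuple[float, float, float, float]:
    """Coarse 4-D grid search for the double-exponential decay parameters.

    Evaluates the residual sum of squares of
    ``1 - a1*(1-exp(-t/T1)) - a2*(1-exp(-t/T2))`` (amplitudes as fractions)
    on the full Cartesian grid and returns the best (P1%, P2%, T1, T2).
    The quadratic expansion of the rss in the amplitudes is used purely to
    evaluate the grid cheaply; every grid point is still visited.
    """
    depth = 1.0 - np.asarray(y, dtype=float)
    u_fast = 1.0 - np.exp(-t[None, :] / tc_fast_grid[:, None])  # (F, n)
    u_slow = 1.0 - np.exp(-t[None, :] / tc_slow_grid[:, None])  # (S, n)
    g11 = np.einsum("fn,fn->f", u_fast, u_fast)
    g22 = np.einsum("sn,sn->s", u_slow, u_slow)
    g12 = np.einsum("fn,sn->fs", u_fast, u_slow)
    b1 = u_fast @ depth
    b2 = u_slow @ depth
    a = p_grid[:, None, None, None] / 100.0
    b = p_grid[None, :, None, None] / 100.0
    rss = (
        a * a * g11[None, None, :, None]
        + b * b * g22[None, None, None, :]
        + 2 * a * b * g12[None, None, :, :]
        - 2 * a * b1[None, None, :, None]
        - 2 * b * b2[None, None, None, :]
    )
    i, j, f, s = np.unravel_index(np.argmin(rss), rss.shape)
    return (
        float(p_grid[i]),
        float(p_grid[j]),
        float(tc_fast_grid[f]),
        float(tc_slow_grid[s]),
    )
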