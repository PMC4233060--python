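"""Independent brute-force oracles used to check the fast implementations.

Everything here deliberately avoids the code paths under test: sums are
naive double loops, the likelihood is maximised numerically on a lattice,
zone counts are recomputed by coordinate comparison against raw points.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy


def naive_rect_sum(counts: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> int:
    """Double-loop sum over inclusive index ranges."""
    total = 0
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            total += int(counts[r, c])
    return total


def lattice_log_numerator(c: int, n: int, C: int, N: int, n_grid: int = 4001) -> float:
    """sup over p >= q of the binomial log-likelihood, by lattice search.

    The lattice is a fine uniform grid over [0, 1] augmented with the three
    stationary probabilities c/n, (C-c)/(N-n) and C/N; the p>q supremum
    equals the maximum over the closed region p >= q by continuity.  Uses a
    running prefix-max over q for each p, so cost is linear in the lattice.
    """
    extra = [C / N]
    if n > 0:
        extra.append(c / n)
    if N - n > 0:
        extra.append((C - c) / (N - n))
    grid = np.unique(np.concatenate([np.linspace(0.0, 1.0, n_grid), extra]))
    lp = xlogy(c, grid) + xlogy(n - c, 1.0 - grid)          # in-zone term as f(p)
    lq = xlogy(C - c, grid) + xlogy((N - n) - (C - c), 1.0 - grid)  # out-zone as f(q)
    best_lq = np.maximum.accumulate(lq)  # max over q <= p
    return float(np.max(lp + best_lq))


def naive_point_scan(
    points_xy: np.ndarray,
    is_case: np.ndarray,
    resolution: float,
    n_cols: int,
    n_rows: int,
    widths,
    heights,
    max_zone_fraction: float = 0.5,
):
    """Recount every rectangular window directly from point coordinates.

    Returns a dict mapping (col_min, col_max, row_min, row_max) to (c, n).
    Windows with n == 0 or n > max_zone_fraction*N are omitted,
    mirroring the candidate filter of the scanner under test.
    """
    x = points_xy[:, 0]
    y = points_xy[:, 1]
    N = len(x)
    C = int(is_case.sum())
    out = {}
    for h in heights:
        for w in widths:
            for r0 in range(0, n_rows - h + 1):
                for c0 in range(0, n_cols - w + 1):
                    in_win = (
                        (x >= c0 * resolution)
                        & (x < (c0 + w) * resolution)
                        & (y >= r0 * resolution)
                        & (y < (r0 + h) * resolution)
                    )
                    n = int(in_win.sum())
                    if n < 1 or n > max_zone_fraction * N:
                        continue
                    c = int((in_win & is_case).sum())
                    out[(c0, c0 + w - 1, r0, r0 + h - 1)] = (c, n)
    return out, C, N


def permutation_trend_pvalue(
    table_2xk: np.ndarray, scores, n_perm: int, seed: int
) -> float:
    """Two-sided permutation p-value for the score-sum trend statistic.

    Relabels which individuals are cases, holding the level margins and the
    case total fixed (multivariate hypergeometric), and compares |T - E T|.
    """
    t = np.asarray(table_2xk, dtype=np.int64)
    s = np.asarray(scores, dtype=float)
    n_k = t.sum(axis=0)
    cases = int(t[0].sum())
    obs = float(np.dot(s, t[0]))
    expect = cases * float(np.dot(s, n_k)) / n_k.sum()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = rng.multivariate_hypergeometric(n_k, cases)
        if abs(float(np.dot(s, r)) - expect) >= abs(obs - expect) - 1e-9:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def best_nonoverlapping_pair_value(candidates) -> float:
    """Exhaustive best total statistic over all disjoint candidate pairs."""
    best = -np.inf
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if not a.zone.overlaps(b.zone):
                best = max(best, a.log_numerator + b.log_numerator)
    return best
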