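"""Data-driven cluster search on the equal-area grid.

Every axis-aligned rectangular window of the configured sizes is slid across
the grid; for each window the case and individual counts come from two
summed-area tables (four array reads each), and the window is scored with
the numerator of Kulldorff's binomial likelihood ratio.  With ``c`` cases
among ``n`` individuals in the zone, ``C`` cases among ``N`` individuals in
total, and the in-/out-of-zone case probabilities estimated as ``p̂ = c/n``
and ``q̂ = (C−c)/(N−n)``, the log numerator is

    c·log p̂ + (n−c)·log(1−p̂) + (C−c)·log q̂ + (N−n−C+c)·log(1−q̂)   if p̂ > q̂

and otherwise the null supremum ``C·log(C/N) + (N−C)·log(1−C/N)`` (the
likelihood maximised at a common case probability).  The denominator of the
ratio is the same for every zone, so ranking by the numerator ranks the
zones.  Zones are ranked, deduplicated to non-overlapping reports, and given
Monte-Carlo p-values by permutation of case labels over locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .laea_grid import CountGrid, PrefixGrid, RectZone, integral_image

__all__ = [
    "ZoneCounts",
    "ClusterCandidate",
    "ScanConfig",
    "kulldorff_log_numerator",
    "scan",
    "monte_carlo_pvalue",
    "attach_mc_pvalues",
    "select_top_nonoverlapping",
    "naive_scan_op_count",
]


@dataclass(frozen=True)
class ZoneCounts:
    """The four counts that determine the scan statistic for one zone."""

    c: int  # cases in zone
    n: int  # individuals (cases + controls, or population) in zone
    C: int  # total cases
    N: int  # total individuals

    def __post_init__(self) -> None:
        if not (0 <= self.c <= self.n <= self.N):
            raise ValueError(f"require 0 <= c <= n <= N, got {self}")
        if not (self.c <= self.C <= self.N):
            raise ValueError(f"require c <= C <= N, got {self}")
        if self.C - self.c > self.N - self.n:
            raise ValueError(f"more out-of-zone cases than out-of-zone individuals: {self}")


@dataclass
class ClusterCandidate:
    zone: RectZone
    counts: ZoneCounts
    log_numerator: float
    rank: int = 0
    mc_pvalue: float | None = None


@dataclass
class ScanConfig:
    """Scan parameters.

    Several window sizes are scanned so small and large clusters can both be
    detected; ``max_zone_fraction`` caps the zone at half the study
    population by default (the usual "zone smaller than its complement"
    convention).
    """

    window_widths: Sequence[int] = tuple(range(1, 11))
    window_heights: Sequence[int] = tuple(range(1, 11))
    step: int = 1
    max_zone_fraction: float = 0.5
    n_permutations: int = 999
    seed: int = 0
    top_k: int = 5

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.window_widths) or any(h < 1 for h in self.window_heights):
            raise ValueError("window sizes must be >= 1")
        if not (0.0 < self.max_zone_fraction <= 1.0):
            raise ValueError("max_zone_fraction must be in (0, 1]")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def _log_numerator_arrays(c, n, C: int, N: int) -> np.ndarray:
    """Vectorised log numerator; 0·log 0 handled via xlogy."""
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    null_value = xlogy(C, C / N) + xlogy(N - C, 1.0 - C / N)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_in = np.where(n > 0, c / np.maximum(n, 1), 0.0)
        n_out = N - n
        q_out = np.where(n_out > 0, (C - c) / np.maximum(n_out, 1), 0.0)
        alt = (
            xlogy(c, p_in)
            + xlogy(n - c, 1.0 - p_in)
            + xlogy(C - c, q_out)
            + xlogy(n_out - (C - c), 1.0 - q_out)
        )
    return np.where(p_in > q_out, alt, null_value)


def kulldorff_log_numerator(z: ZoneCounts) -> float:
    """Log of the supremum (over p > q) of the likelihood-ratio numerator.

    Falls back to the null supremum when the zone shows no case excess
    (p̂ ≤ q̂), so the statistic never rewards deficits.
    """
    if z.N <= 0:
        raise ValueError("N must be positive")
    if z.n >= z.N:
        raise ValueError("a zone covering the whole study region is not a candidate")
    return float(_log_numerator_arrays(z.c, z.n, z.C, z.N))


def scan(
    case_prefix: PrefixGrid,
    control_prefix: PrefixGrid,
    cfg: ScanConfig,
    max_candidates: int | None = None,
) -> list[ClusterCandidate]:
    """Score every rectangular window and return ranked candidates.

    ``control_prefix`` may hold either explicit controls or population at
    risk; in either case ``n`` is cases+controls in the zone and ``N`` the
    grand total.  Windows with no individuals, or covering more than
    ``max_zone_fraction`` of N, are not candidates.  Candidates are sorted by
    decreasing statistic with deterministic tie-breaking (smaller area first,
    then lower-left position).  ``max_candidates`` truncates the returned
    list after ranking (the ranking itself always considers every window).
    """
    if case_prefix.spec != control_prefix.spec:
        raise ValueError("case and control grids must share a GridSpec")
    spec = case_prefix.spec
    C = int(case_prefix.cumulative[-1, -1])
    total_controls = int(control_prefix.cumulative[-1, -1])
    N = C + total_controls
    if C < 1:
        raise ValueError("no cases on the grid")
    if total_controls < 1:
        raise ValueError("no controls / population on the grid")

    n_cap = cfg.max_zone_fraction * N
    stats, cs, ns, rows, cols, widths, heights = [], [], [], [], [], [], []
    for h in cfg.window_heights:
        for w in cfg.window_widths:
            case_sums = case_prefix.window_sums(w, h, cfg.step)
            if case_sums.size == 0:
                continue
            ctrl_sums = control_prefix.window_sums(w, h, cfg.step)
            n = case_sums + ctrl_sums
            ll = _log_numerator_arrays(case_sums, n, C, N)
            keep = (n >= 1) & (n <= n_cap)
            if not np.any(keep):
                continue
            i, j = np.nonzero(keep)
            stats.append(ll[keep])
            cs.append(case_sums[keep])
            ns.append(n[keep])
            rows.append(i * cfg.step + spec.row_range[0])
            cols.append(j * cfg.step + spec.col_range[0])
            widths.append(np.full(i.shape, w))
            heights.append(np.full(i.shape, h))

    if not stats:
        return []
    stat = np.concatenate(stats)
    c_arr = np.concatenate(cs)
    n_arr = np.concatenate(ns)
    row0 = np.concatenate(rows)
    col0 = np.concatenate(cols)
    w_arr = np.concatenate(widths)
    h_arr = np.concatenate(heights)
    area = w_arr * h_arr

    # sort: statistic desc, then area asc, then (row_min, col_min, h, w) asc
    order = np.lexsort((w_arr, h_arr, col0, row0, area, -stat))
    if max_candidates is not None:
        order = order[:max_candidates]

    out = []
    for rank, idx in enumerate(order, start=1):
        zone = RectZone(
            col_min=int(col0[idx]),
            col_max=int(col0[idx] + w_arr[idx] - 1),
            row_min=int(row0[idx]),
            row_max=int(row0[idx] + h_arr[idx] - 1),
        )
        out.append(
            ClusterCandidate(
                zone=zone,
                counts=ZoneCounts(c=int(c_arr[idx]), n=int(n_arr[idx]), C=C, N=N),
                log_numerator=float(stat[idx]),
                rank=rank,
            )
        )
    return out


def _best_stat_null_distribution(
    case_grid: CountGrid, control_grid: CountGrid, cfg: ScanConfig, rng: np.random.Generator
) -> np.ndarray:
    """Best-over-all-windows statistic under R case-label permutations.

    A permutation reassigns which of the N individuals are cases, holding
    every location and the total C fixed: per-cell case counts are a
    multivariate hypergeometric draw from the per-cell individual totals.
    """
    totals = case_grid.counts + control_grid.counts
    C = int(case_grid.counts.sum())
    N = int(totals.sum())
    nr, nc = totals.shape
    flat = totals.ravel().astype(np.int64)
    R = cfg.n_permutations

    perm_cases = np.empty((R, flat.size), dtype=np.int64)
    for r in range(R):
        perm_cases[r] = rng.multivariate_hypergeometric(flat, C, method="marginals")
    perm_cases = perm_cases.reshape(R, nr, nc)

    # batched zero-padded summed-area tables: (R, nr+1, nc+1)
    cum = np.zeros((R, nr + 1, nc + 1), dtype=np.int64)
    np.cumsum(perm_cases, axis=1, out=cum[:, 1:, 1:])
    np.cumsum(cum[:, 1:, 1:], axis=2, out=cum[:, 1:, 1:])
    tot_cum = np.zeros((nr + 1, nc + 1), dtype=np.int64)
    np.cumsum(totals, axis=0, out=tot_cum[1:, 1:])
    np.cumsum(tot_cum[1:, 1:], axis=1, out=tot_cum[1:, 1:])

    n_cap = cfg.max_zone_fraction * N
    best = np.full(R, -np.inf)
    s = cfg.step
    for h in cfg.window_heights:
        for w in cfg.window_widths:
            if w > nc or h > nr:
                continue
            r0 = np.arange(0, nr - h + 1, s)
            c0 = np.arange(0, nc - w + 1, s)
            n_win = (
                tot_cum[np.ix_(r0 + h, c0 + w)]
                - tot_cum[np.ix_(r0, c0 + w)]
                - tot_cum[np.ix_(r0 + h, c0)]
                + tot_cum[np.ix_(r0, c0)]
            )
            valid = (n_win >= 1) & (n_win <= n_cap)
            if not np.any(valid):
                continue
            i, j = np.nonzero(valid)
            c_win = (
                cum[:, (r0 + h)[i], (c0 + w)[j]]
                - cum[:, r0[i], (c0 + w)[j]]
                - cum[:, (r0 + h)[i], c0[j]]
                + cum[:, r0[i], c0[j]]
            )
            ll = _log_numerator_arrays(c_win, n_win[i, j][None, :], C, N)
            np.maximum(best, ll.max(axis=1), out=best)
    return best


def monte_carlo_pvalue(
    observed_stat: float,
    case_grid: CountGrid,
    control_grid: CountGrid,
    cfg: ScanConfig,
) -> float:
    """Monte-Carlo p-value for one observed statistic.

    ``p = (1 + #{permutations whose best statistic ≥ observed}) /
    (1 + n_permutations)``; the permutation null relabels case/control
    status over the fixed locations.
    """
    if cfg.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    best = _best_stat_null_distribution(case_grid, control_grid, cfg, rng)
    return float((1 + np.count_nonzero(best >= observed_stat)) / (1 + cfg.n_permutations))


def attach_mc_pvalues(
    candidates: Sequence[ClusterCandidate],
    case_grid: CountGrid,
    control_grid: CountGrid,
    cfg: ScanConfig,
) -> list[ClusterCandidate]:
    """Give each candidate a p-value against one shared permutation null."""
    if cfg.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    best = _best_stat_null_distribution(case_grid, control_grid, cfg, rng)
    R = cfg.n_permutations
    for cand in candidates:
        cand.mc_pvalue = float(
            (1 + np.count_nonzero(best >= cand.log_numerator)) / (1 + R)
        )
    return list(candidates)


def select_top_nonoverlapping(
    candidates: Sequence[ClusterCandidate], k: int
) -> list[ClusterCandidate]:
    """Greedy top-k: keep a candidate iff it shares no cell with kept ones."""
    kept: list[ClusterCandidate] = []
    for cand in candidates:
        if len(kept) >= k:
            break
        if any(cand.zone.overlaps(prev.zone) for prev in kept):
            continue
        kept.append(cand)
    return kept


def naive_scan_op_count(positions: int, sizes: int, individuals: int) -> int:
    """Distance evaluations a point-based circular scan would need.

    Every window position, at every window size, recomputes the distance
    from the window centre to every individual.
    """
    return int(positions) * int(sizes) * int(individuals)
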