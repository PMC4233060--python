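"""Density-matched virtual-control generation.

When no enrolled control group exists, controls can be sampled from the
population surface itself, at local population densities comparable to
those where the cases live: otherwise a purely uniform draw would make the
(mostly urban) cases look "clustered" against rural controls.  The match is
done by binning inhabited cells into population-per-cell quantile bins,
measuring the case distribution over those bins, and sampling each control
by first drawing a bin with the case weights, then a cell within the bin
proportionally to its population, then a uniform position inside the cell.
Replicated series make the sampling noise itself measurable: each series is
analysed separately and the per-class results are aggregated across series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exposure_analysis import ExposureReport
from .laea_grid import CountGrid, PointRecord

__all__ = [
    "DensityProfile",
    "ControlSeries",
    "density_profile",
    "sample_series",
    "aggregate_series",
]


@dataclass(frozen=True)
class DensityProfile:
    """Population-per-cell bin edges and the case weight in each bin."""

    bin_edges: np.ndarray  # strictly increasing interior cutpoints
    case_bin_weights: np.ndarray  # sums to 1

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if abs(float(self.case_bin_weights.sum()) - 1.0) > 1e-9:
            raise ValueError("case_bin_weights must sum to 1")


@dataclass
class ControlSeries:
    series_id: int
    points: list[PointRecord]
    seed: int


def _cell_population(pop_grid: CountGrid, cells: np.ndarray) -> np.ndarray:
    spec = pop_grid.spec
    return pop_grid.counts[
        cells[:, 1] - spec.row_range[0], cells[:, 0] - spec.col_range[0]
    ]


def density_profile(
    pop_grid: CountGrid, case_cells: Sequence[tuple[int, int]], n_bins: int = 10
) -> DensityProfile:
    """Quantile-bin the inhabited cells and weight bins by where cases live.

    Bins are deciles (by default) of population over inhabited cells; ties
    in the quantiles collapse duplicate edges, so sparse surfaces may yield
    fewer effective bins.
    """
    pop = pop_grid.counts[pop_grid.counts > 0].astype(float)
    if pop.size == 0:
        raise ValueError("population grid has no inhabited cells")
    qs = np.quantile(pop, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    case_cells = np.asarray(case_cells, dtype=int)
    case_pop = _cell_population(pop_grid, case_cells).astype(float)
    if np.any(case_pop <= 0):
        raise ValueError("some cases fall in uninhabited cells")
    bins = np.searchsorted(edges, case_pop, side="left")
    weights = np.bincount(bins, minlength=edges.size + 1).astype(float)
    weights /= weights.sum()
    return DensityProfile(bin_edges=edges, case_bin_weights=weights)


def sample_series(
    pop_grid: CountGrid,
    profile: DensityProfile,
    size: int,
    n_series: int,
    seed: int,
) -> list[ControlSeries]:
    """Draw ``n_series`` independent series of ``size`` virtual controls.

    Each series has its own RNG stream derived from ``(seed, series_id)``,
    so any single series is reproducible without generating the others.
    Raises if a bin carries positive case weight but holds no inhabited
    cell (the surface cannot supply density-matched controls there).
    """
    spec = pop_grid.spec
    rows, cols = np.nonzero(pop_grid.counts)
    if rows.size == 0:
        raise ValueError("population grid has no inhabited cells")
    cell_pop = pop_grid.counts[rows, cols].astype(float)
    cell_bin = np.searchsorted(profile.bin_edges, cell_pop, side="left")
    n_bins = profile.case_bin_weights.size
    per_bin_idx = [np.nonzero(cell_bin == b)[0] for b in range(n_bins)]
    for b, idx in enumerate(per_bin_idx):
        if profile.case_bin_weights[b] > 0 and idx.size == 0:
            raise ValueError(f"density bin {b} has positive case weight but no inhabited cells")
    per_bin_p = [
        cell_pop[idx] / cell_pop[idx].sum() if idx.size else None for idx in per_bin_idx
    ]

    res = spec.resolution_m
    out: list[ControlSeries] = []
    for series_id in range(n_series):
        rng = np.random.default_rng([seed, series_id])
        points: list[PointRecord] = []
        if size > 0:
            bins = rng.choice(n_bins, size=size, p=profile.case_bin_weights)
            chosen = np.empty(size, dtype=np.int64)
            for b in np.unique(bins):
                mask = bins == b
                chosen[mask] = rng.choice(
                    per_bin_idx[b], size=int(mask.sum()), p=per_bin_p[b]
                )
            u = rng.uniform(0.0, 1.0, size=(size, 2))
            east = (cols[chosen] + spec.col_range[0] + u[:, 0]) * res
            north = (rows[chosen] + spec.row_range[0] + u[:, 1]) * res
            points = [
                PointRecord(
                    id=f"vc{series_id}_{i}",
                    group="control",
                    easting=float(east[i]),
                    northing=float(north[i]),
                )
                for i in range(size)
            ]
        out.append(ControlSeries(series_id=series_id, points=points, seed=seed))
    return out


def aggregate_series(
    per_series_reports: Sequence[Sequence[ExposureReport]], alpha: float = 0.05
) -> dict:
    """Summarise per-class exposure results across control series.

    For each class and level: median odds ratio, 2.5/97.5 percentiles across
    series, and the fraction of series significant after correction.
    """
    if not per_series_reports:
        raise ValueError("no series reports to aggregate")
    by_class: dict[str, list[ExposureReport]] = {}
    for series in per_series_reports:
        for rep in series:
            by_class.setdefault(rep.class_id, []).append(rep)

    summary: dict[str, dict] = {}
    for class_id, reps in sorted(by_class.items()):
        usable = [r for r in reps if r.skipped is None]
        entry: dict = {"n_series": len(usable)}
        for lv in ("H", "M", "L"):
            ors = np.array(
                [r.odds_ratios[lv].oddsratio for r in usable], dtype=float
            )
            ok = np.isfinite(ors)
            entry[lv] = {
                "median_or": float(np.median(ors[ok])) if ok.any() else float("nan"),
                "or_p2.5": float(np.percentile(ors[ok], 2.5)) if ok.any() else float("nan"),
                "or_p97.5": float(np.percentile(ors[ok], 97.5)) if ok.any() else float("nan"),
            }
        sig = [
            r.adjusted_p is not None and r.adjusted_p < alpha for r in usable
        ]
        entry["fraction_significant"] = float(np.mean(sig)) if usable else float("nan")
        summary[class_id] = entry
    return summary
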