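"""Hypothesis-driven testing of point-located environmental factors.

Environmental point sources (factories, waste dumps, sampled curves or
surfaces) are grouped into classes of entities sharing a characteristic,
e.g. all plants emitting one chemical.  For each class, every individual is
assigned an exposure level from the distance between their grid cell's
centre and the nearest entity of the class: High for distance ≤ r_H, Medium
up to r_M, Low up to r_L, Unexposed beyond (bands closed on the near side).
Each level is then compared with the unexposed stratum in a 2×2
case/control table: odds ratio with a 95% Woolf (log-method) confidence
interval, plus a Cochran–Armitage trend test across the ordered levels for
a dose-response signal.  Classes are tested one at a time, so the p-values
are corrected for multiple comparisons across classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .laea_grid import GridSpec

__all__ = [
    "EnvEntity",
    "EntityClass",
    "ExposureThresholds",
    "OddsRatioResult",
    "ExposureReport",
    "LEVELS",
    "nearest_entity_distance",
    "assign_exposure",
    "contingency_tables",
    "odds_ratio_ci",
    "trend_test",
    "analyze_classes",
]

#: exposure levels ordered by increasing dose (U = unexposed)
LEVELS = ("U", "L", "M", "H")


@dataclass(frozen=True)
class EnvEntity:
    entity_id: str
    easting: float
    northing: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.easting) and np.isfinite(self.northing)):
            raise ValueError(f"entity {self.entity_id!r}: non-finite coordinates")


@dataclass
class EntityClass:
    class_id: str
    members: frozenset[str]
    name: str = ""


@dataclass(frozen=True)
class ExposureThresholds:
    """Distance cut-offs (metres) for the H/M/L bands; 0 < r_H < r_M < r_L."""

    r_H: float
    r_M: float
    r_L: float

    def __post_init__(self) -> None:
        if not (0.0 < self.r_H < self.r_M < self.r_L):
            raise ValueError("require 0 < r_H < r_M < r_L")


@dataclass
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False
    undefined: bool = False


@dataclass
class ExposureReport:
    class_id: str
    tables: dict  # level -> 2x2 [[cases_level, cases_U], [controls_level, controls_U]]
    odds_ratios: dict  # level -> OddsRatioResult
    trend_statistic: float
    trend_p: float
    p_value: float
    adjusted_p: float | None = None
    level_counts: dict = field(default_factory=dict)
    skipped: str | None = None


def nearest_entity_distance(
    cells: Sequence[tuple[int, int]],
    entities: Iterable[EnvEntity],
    spec: GridSpec,
) -> np.ndarray:
    """Planar distance from each cell centre to the closest entity.

    Distances are Euclidean in the LAEA plane (the projection is equal-area
    and, over the band widths in play, its distance distortion is far below
    the half-cell quantisation already accepted by the grid approach).
    """
    ents = list(entities)
    if not ents:
        raise ValueError("empty entity set")
    cells_arr = np.asarray(cells, dtype=float)
    centres = np.column_stack(spec.cell_centre(cells_arr[:, 0], cells_arr[:, 1]))
    coords = np.array([(e.easting, e.northing) for e in ents], dtype=float)
    tree = cKDTree(coords)
    dist, _ = tree.query(centres, k=1)
    return np.asarray(dist, dtype=float)


def assign_exposure(distance, thresholds: ExposureThresholds) -> np.ndarray:
    """Map distances to levels H/M/L/U; a point exactly at a cut-off takes
    the nearer (higher-exposure) band."""
    d = np.asarray(distance, dtype=float)
    edges = [thresholds.r_H, thresholds.r_M, thresholds.r_L]
    idx = np.searchsorted(edges, d, side="left")  # 0:H 1:M 2:L 3:U
    out = np.array(["H", "M", "L", "U"], dtype="<U1")[idx]
    if out.ndim == 0:
        return str(out)
    return out


def contingency_tables(
    case_levels: Sequence[str], control_levels: Sequence[str]
) -> dict[str, np.ndarray]:
    """One 2×2 table per exposed level X vs the unexposed stratum.

    ``table[X] = [[cases at X, cases at U], [controls at X, controls at U]]``;
    individuals at the other levels do not enter that table.
    """
    case_levels = np.asarray(case_levels)
    control_levels = np.asarray(control_levels)
    case_n = {lv: int(np.count_nonzero(case_levels == lv)) for lv in LEVELS}
    ctrl_n = {lv: int(np.count_nonzero(control_levels == lv)) for lv in LEVELS}
    return {
        lv: np.array(
            [[case_n[lv], case_n["U"]], [ctrl_n[lv], ctrl_n["U"]]], dtype=np.int64
        )
        for lv in ("H", "M", "L")
    }


def odds_ratio_ci(table: np.ndarray, alpha: float = 0.05) -> OddsRatioResult:
    """Odds ratio with the Woolf log-method confidence interval.

    OR = ad/bc and ``exp(ln OR ± z·√(1/a+1/b+1/c+1/d))``.  A zero cell
    triggers the Haldane–Anscombe 0.5 correction on all four cells and the
    result is flagged; an all-zero row leaves the OR undefined (flagged, not
    raised, so one degenerate class cannot abort a multi-class run).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 array")
    if np.any(t.sum(axis=1) == 0):
        return OddsRatioResult(np.nan, np.nan, np.nan, undefined=True)
    corrected = bool(np.any(t == 0))
    if corrected:
        t = t + 0.5
    a, b, c, d = t.ravel()
    or_ = (a * d) / (b * c)
    z = norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        oddsratio=float(or_),
        ci_low=float(or_ * np.exp(-z * se)),
        ci_high=float(or_ * np.exp(z * se)),
        continuity_corrected=corrected,
    )


def trend_test(levels_table: np.ndarray, scores: Sequence[float] = (0, 1, 2, 3)):
    """Cochran–Armitage test for trend in case proportion across the
    ordered exposure levels U < L < M < H (integer scores 0..3).

    ``levels_table`` is 2×k: row 0 cases, row 1 controls, columns in dose
    order.  Returns (standardized statistic, two-sided normal p).  The
    statistic is positive when the case proportion rises with dose.
    """
    t = np.asarray(levels_table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] != len(scores):
        raise ValueError("levels_table must be 2 x len(scores)")
    s = np.asarray(scores, dtype=float)
    n_k = t.sum(axis=0)
    total = n_k.sum()
    cases = t[0].sum()
    if total == 0 or cases == 0 or cases == total:
        return 0.0, 1.0
    p_bar = cases / total
    num = float(np.dot(s, t[0]) - p_bar * np.dot(s, n_k))
    s_bar = np.dot(s, n_k) / total
    # variance of the score sum under permutation of case labels
    # (hypergeometric, hence the N/(N-1) finite-population factor)
    var = (
        p_bar
        * (1.0 - p_bar)
        * float(np.dot((s - s_bar) ** 2, n_k))
        * (total / (total - 1.0) if total > 1 else 1.0)
    )
    if var <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def _class_report(
    class_id: str,
    case_levels: np.ndarray,
    control_levels: np.ndarray,
) -> ExposureReport:
    tables = contingency_tables(case_levels, control_levels)
    ors = {lv: odds_ratio_ci(tables[lv]) for lv in ("H", "M", "L")}
    counts2x4 = np.array(
        [
            [int(np.count_nonzero(case_levels == lv)) for lv in LEVELS],
            [int(np.count_nonzero(control_levels == lv)) for lv in LEVELS],
        ],
        dtype=np.int64,
    )
    z, p = trend_test(counts2x4)
    return ExposureReport(
        class_id=class_id,
        tables=tables,
        odds_ratios=ors,
        trend_statistic=z,
        trend_p=p,
        p_value=p,
        level_counts={
            "cases": dict(zip(LEVELS, counts2x4[0].tolist())),
            "controls": dict(zip(LEVELS, counts2x4[1].tolist())),
        },
    )


def analyze_classes(
    classes: Mapping[str, EntityClass],
    entities: Mapping[str, EnvEntity],
    case_cells: Sequence[tuple[int, int]],
    control_cells: Sequence[tuple[int, int]],
    thresholds: ExposureThresholds,
    spec: GridSpec,
    correction: str = "bonferroni",
) -> list[ExposureReport]:
    """Test each entity class separately and correct across classes.

    ``correction`` is ``"bonferroni"`` (family-wise, default) or ``"fdr_bh"``
    (Benjamini–Hochberg).  Classes with no located entities are skipped with
    a recorded reason and excluded from the correction count.  Testing class
    by class keeps per-test power high at the price of the usual multiplicity
    burden, which is exactly what the correction addresses.
    """
    if correction not in ("bonferroni", "fdr_bh"):
        raise ValueError(f"unknown correction {correction!r}")
    case_cells = np.asarray(case_cells, dtype=int)
    control_cells = np.asarray(control_cells, dtype=int)
    # distances are per unique cell; individuals inherit their cell's level
    all_cells = np.vstack([case_cells, control_cells])
    uniq, inverse = np.unique(all_cells, axis=0, return_inverse=True)

    reports: list[ExposureReport] = []
    for class_id in sorted(classes):
        cls = classes[class_id]
        members = [entities[eid] for eid in sorted(cls.members) if eid in entities]
        if not members:
            reports.append(
                ExposureReport(
                    class_id=class_id,
                    tables={},
                    odds_ratios={},
                    trend_statistic=np.nan,
                    trend_p=np.nan,
                    p_value=np.nan,
                    skipped="no located entities in class",
                )
            )
            continue
        dist = nearest_entity_distance([tuple(c) for c in uniq], members, spec)
        levels = assign_exposure(dist, thresholds)[inverse]
        case_levels = levels[: len(case_cells)]
        control_levels = levels[len(case_cells):]
        reports.append(_class_report(class_id, case_levels, control_levels))

    tested = [r for r in reports if r.skipped is None]
    if tested:
        pvals = np.array([r.p_value for r in tested])
        adjusted = multipletests(pvals, method=correction)[1]
        for r, ap in zip(tested, adjusted):
            r.adjusted_p = float(ap)
    return reports
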