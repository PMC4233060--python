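"""Equal-area grid data model.

Points located in WGS84 (or already in ETRS89-LAEA metres) are projected onto
a square grid aligned with the EPSG:3035 plane.  Because the projection is
equal-area, every cell at a given resolution covers exactly ``resolution²``
of ground area, so per-cell counts are directly comparable across the map.

The module provides the grid types (:class:`GridSpec`, :class:`CountGrid`,
:class:`PrefixGrid`, :class:`RectZone`), point-to-cell projection, GEOSTAT
cell identifiers, summed-area tables for O(1) rectangle counting, and the
case-density cell-flagging rule used for map display.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

from ._projection import laea_to_wgs84, wgs84_to_laea

__all__ = [
    "GridSpec",
    "PointRecord",
    "CountGrid",
    "PrefixGrid",
    "RectZone",
    "CellCategory",
    "wgs84_to_laea",
    "laea_to_wgs84",
    "point_to_cell",
    "cell_id",
    "parse_cell_id",
    "build_count_grid",
    "integral_image",
    "rect_sum",
    "flag_cells",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an equal-area grid.

    Cell ``(col, row)`` covers the half-open square
    ``[col·res, (col+1)·res) × [row·res, (row+1)·res)`` in (easting, northing)
    metres, so a 1 km cell with ``col=3610`` starts at easting 3 610 000 m.
    ``col_range``/``row_range`` are inclusive index bounds of the covered
    region.
    """

    col_range: tuple[int, int]
    row_range: tuple[int, int]
    resolution_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.resolution_m <= 0:
            raise ValueError("resolution_m must be positive")
        if self.col_range[0] > self.col_range[1] or self.row_range[0] > self.row_range[1]:
            raise ValueError("col_range/row_range must be non-empty")

    @property
    def n_cols(self) -> int:
        return self.col_range[1] - self.col_range[0] + 1

    @property
    def n_rows(self) -> int:
        return self.row_range[1] - self.row_range[0] + 1

    def contains_cell(self, col: int, row: int) -> bool:
        return (
            self.col_range[0] <= col <= self.col_range[1]
            and self.row_range[0] <= row <= self.row_range[1]
        )

    def cell_centre(self, col, row):
        """LAEA coordinates of the centre of cell(s) (col, row)."""
        res = self.resolution_m
        return (np.asarray(col) + 0.5) * res, (np.asarray(row) + 0.5) * res

    def new_counts(self) -> np.ndarray:
        return np.zeros((self.n_rows, self.n_cols), dtype=np.int64)


@dataclass(frozen=True)
class PointRecord:
    """A single located individual: a case or a control.

    Exactly one coordinate pair is set: (lon, lat) in WGS84 degrees, or
    (easting, northing) in LAEA metres.
    """

    id: str
    group: str
    lon: float | None = None
    lat: float | None = None
    easting: float | None = None
    northing: float | None = None

    def __post_init__(self) -> None:
        geo = self.lon is not None and self.lat is not None
        planar = self.easting is not None and self.northing is not None
        if geo == planar:
            raise ValueError(
                f"point {self.id!r}: exactly one of (lon,lat) or (easting,northing) required"
            )
        if geo:
            if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
                raise ValueError(f"point {self.id!r}: non-finite coordinates")
            if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
                raise ValueError(f"point {self.id!r}: lon/lat out of range")
        else:
            if not (np.isfinite(self.easting) and np.isfinite(self.northing)):
                raise ValueError(f"point {self.id!r}: non-finite coordinates")

    def to_laea(self) -> tuple[float, float]:
        if self.easting is not None:
            return float(self.easting), float(self.northing)
        return wgs84_to_laea(self.lon, self.lat)


class CellCategory(IntEnum):
    """Display category of a grid cell, from population and case counts."""

    UNINHABITED = 0
    INHABITED = 1
    HAS_CASES = 2
    FLAGGED = 3


@dataclass
class CountGrid:
    """Per-cell integer counts (cases, controls or population) on a grid."""

    spec: GridSpec
    counts: np.ndarray  # shape (n_rows, n_cols), int
    label: str = "cases"
    rejects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = (self.spec.n_rows, self.spec.n_cols)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != grid shape {expected}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


@dataclass
class PrefixGrid:
    """Summed-area table of a :class:`CountGrid`.

    ``cumulative[r, c]`` holds the sum of counts over rows ``< r`` and
    columns ``< c`` (a zero-padded inclusive prefix), so any rectangle sum
    costs exactly four array reads.  ``reads`` counts element reads for the
    complexity contract of the scanner.
    """

    spec: GridSpec
    cumulative: np.ndarray  # shape (n_rows + 1, n_cols + 1)
    reads: int = 0

    @property
    def total(self) -> int:
        self.reads += 1
        return int(self.cumulative[-1, -1])

    def window_sums(self, width: int, height: int, step: int = 1) -> np.ndarray:
        """Sums of every ``width×height`` window at the given step.

        Returns an array of shape (n_row_positions, n_col_positions); entry
        (i, j) is the count in the window whose lower-left cell is local
        (row=i·step, col=j·step).  Four reads per window.
        """
        p = self.cumulative
        nr, nc = self.spec.n_rows, self.spec.n_cols
        if width < 1 or height < 1 or width > nc or height > nr:
            return np.zeros((0, 0), dtype=np.int64)
        r0 = np.arange(0, nr - height + 1, step)
        c0 = np.arange(0, nc - width + 1, step)
        s = (
            p[np.ix_(r0 + height, c0 + width)]
            - p[np.ix_(r0, c0 + width)]
            - p[np.ix_(r0 + height, c0)]
            + p[np.ix_(r0, c0)]
        )
        self.reads += 4 * s.size
        return s


@dataclass(frozen=True)
class RectZone:
    """An axis-aligned rectangle of grid cells, inclusive on all sides."""

    col_min: int
    col_max: int
    row_min: int
    row_max: int

    def __post_init__(self) -> None:
        if self.col_min > self.col_max or self.row_min > self.row_max:
            raise ValueError("empty RectZone")

    @property
    def area_cells(self) -> int:
        return (self.col_max - self.col_min + 1) * (self.row_max - self.row_min + 1)

    def overlaps(self, other: "RectZone") -> bool:
        return not (
            self.col_max < other.col_min
            or other.col_max < self.col_min
            or self.row_max < other.row_min
            or other.row_max < self.row_min
        )

    def corner_coords_laea(self, resolution_m: float) -> list[tuple[float, float]]:
        """The four cell-corner LAEA coordinates, counter-clockwise from
        the upper-left corner of the zone (matching the reporting layout:
        (col_max+1, row_min) first would be another convention; we emit
        (col_max+1·res, row_min·res) style corners of the bounding box)."""
        res = resolution_m
        e0, e1 = self.col_min * res, (self.col_max + 1) * res
        n0, n1 = self.row_min * res, (self.row_max + 1) * res
        return [(e1, n0), (e1, n1), (e0, n1), (e0, n0)]


def point_to_cell(easting, northing, spec: GridSpec):
    """Map LAEA coordinates to (col, row) by flooring; half-open cells.

    A point exactly on an upper cell edge belongs to the next cell.
    Vectorised: accepts arrays and returns integer arrays.
    """
    res = spec.resolution_m
    col = np.floor(np.asarray(easting, dtype=float) / res).astype(np.int64)
    row = np.floor(np.asarray(northing, dtype=float) / res).astype(np.int64)
    if col.ndim == 0:
        return int(col), int(row)
    return col, row


_RES_SUFFIX = {"km": 1000.0, "m": 1.0}
_CELL_ID_RE = re.compile(r"^(\d+)(km|m)N(\d+)E(\d+)$")


def cell_id(col: int, row: int, resolution_m: float = 1000.0) -> str:
    """GEOSTAT-style cell identifier, e.g. ``1kmN2979E3610``."""
    if resolution_m % 1000.0 == 0.0:
        res_txt = f"{int(resolution_m // 1000)}km"
    else:
        res_txt = f"{int(resolution_m)}m"
    return f"{res_txt}N{row}E{col}"


def parse_cell_id(text: str) -> tuple[int, int, float]:
    """Parse a GEOSTAT identifier back to (col, row, resolution_m)."""
    m = _CELL_ID_RE.match(text.strip())
    if m is None:
        raise ValueError(f"not a GEOSTAT cell id: {text!r}")
    value, unit, row, col = m.groups()
    return int(col), int(row), int(value) * _RES_SUFFIX[unit]


def build_count_grid(
    points: Iterable[PointRecord], spec: GridSpec, label: str = "cases"
) -> CountGrid:
    """Project points to cells and tally per-cell counts.

    Out-of-bounds points are never silently dropped: they are collected in
    ``CountGrid.rejects`` as ``(point_id, reason)`` pairs so the run log can
    report them (an audit trail matters in epidemiological work).
    """
    counts = spec.new_counts()
    rejects: list[tuple[str, str]] = []
    for pt in points:
        e, n = pt.to_laea()
        col, row = point_to_cell(e, n, spec)
        if not spec.contains_cell(col, row):
            rejects.append((pt.id, f"cell ({col},{row}) outside grid bounds"))
            continue
        counts[row - spec.row_range[0], col - spec.col_range[0]] += 1
    return CountGrid(spec=spec, counts=counts, label=label, rejects=rejects)


def integral_image(grid: CountGrid) -> PrefixGrid:
    """Summed-area transform: zero-padded 2-D cumulative sums."""
    nr, nc = grid.counts.shape
    cum = np.zeros((nr + 1, nc + 1), dtype=np.int64)
    np.cumsum(grid.counts, axis=0, out=cum[1:, 1:])
    np.cumsum(cum[1:, 1:], axis=1, out=cum[1:, 1:])
    return PrefixGrid(spec=grid.spec, cumulative=cum)


def rect_sum(prefix: PrefixGrid, zone: RectZone) -> int:
    """Sum of counts over ``zone`` from exactly four cumulative-array reads."""
    spec = prefix.spec
    if not (spec.contains_cell(zone.col_min, zone.row_min) and spec.contains_cell(zone.col_max, zone.row_max)):
        raise ValueError(f"zone {zone} outside grid bounds")
    r0 = zone.row_min - spec.row_range[0]
    r1 = zone.row_max - spec.row_range[0] + 1
    c0 = zone.col_min - spec.col_range[0]
    c1 = zone.col_max - spec.col_range[0] + 1
    p = prefix.cumulative
    prefix.reads += 4
    return int(p[r1, c1] - p[r0, c1] - p[r1, c0] + p[r0, c0])


def flag_cells(
    case_grid: CountGrid,
    pop_grid: CountGrid,
    min_cases: int = 2,
    max_pop_per_case: float = 1500.0,
) -> np.ndarray:
    """Classify each cell for display.

    ``FLAGGED``   — at least ``min_cases`` cases *and* population-to-case
                    ratio strictly below ``max_pop_per_case``;
    ``HAS_CASES`` — at least one case, not flagged;
    ``INHABITED`` — population ≥ 1, no cases;
    ``UNINHABITED`` otherwise.
    """
    if case_grid.spec != pop_grid.spec:
        raise ValueError("case and population grids must share a GridSpec")
    cases = case_grid.counts
    pop = pop_grid.counts
    out = np.full(cases.shape, CellCategory.UNINHABITED, dtype=np.int8)
    out[(pop >= 1) & (cases == 0)] = CellCategory.INHABITED
    out[cases >= 1] = CellCategory.HAS_CASES
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cases > 0, pop / np.maximum(cases, 1), np.inf)
    out[(cases >= min_cases) & (ratio < max_pop_per_case)] = CellCategory.FLAGGED
    return out
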