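"""Deterministic synthetic scenarios for end-to-end testing.

Generates abstract rectangular study regions with a population surface, a
case/control cohort with an optional planted rectangular cluster of excess
risk, and scattered environmental entity classes with an optional planted
distance-band proximity effect.  Everything any analysis module consumes
can be produced here, so the whole pipeline is exercisable without any
external download.  All output is reproducible from ``(scenario, seed)``;
each generator draws from its own named substream, so adding draws to one
generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exposure_analysis import EnvEntity, EntityClass, ExposureThresholds, assign_exposure
from .laea_grid import CountGrid, GridSpec, PointRecord, RectZone

__all__ = [
    "SimScenario",
    "simulate_population",
    "simulate_case_control",
    "simulate_entities",
]

# fixed substream tags: population / cases / entities
_STREAM = {"population": 0, "cases": 1, "entities": 2}


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one synthetic study region.

    ``population_model`` is ``uniform`` (every cell identical),
    ``lognormal`` (heavy-tailed per-cell counts, a caricature of mixed
    urban/rural density) or ``cities`` (a few dense centres on a thin
    background).  ``baseline_rate`` is the per-individual case probability
    p₀ outside any planted cluster; inside ``planted_cluster`` the rate is
    multiplied by the relative risk RR (capped at 1).  ``planted_effect``
    plants a distance-band odds-ratio profile for one entity class.
    """

    n_cols: int = 50
    n_rows: int = 50
    resolution_m: float = 1000.0
    population_model: str = "lognormal"
    mean_pop_per_cell: float = 40.0
    baseline_rate: float = 0.01
    planted_cluster: tuple[RectZone, float] | None = None  # (zone, RR)
    planted_effect: tuple[str, dict] | None = None  # (class_id, {"H": OR, ...})
    n_entities: int = 30
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_rate < 1.0):
            raise ValueError("baseline_rate must be in (0,1)")
        if self.planted_cluster is not None and self.planted_cluster[1] <= 0:
            raise ValueError("relative risk must be positive")
        if self.population_model not in ("uniform", "lognormal", "cities"):
            raise ValueError(f"unknown population model {self.population_model!r}")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(
            col_range=(0, self.n_cols - 1),
            row_range=(0, self.n_rows - 1),
            resolution_m=self.resolution_m,
        )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


def simulate_population(scenario: SimScenario) -> CountGrid:
    """Draw the per-cell population surface."""
    rng = scenario.rng("population")
    shape = (scenario.n_rows, scenario.n_cols)
    mean = scenario.mean_pop_per_cell
    if scenario.population_model == "uniform":
        counts = np.full(shape, int(round(mean)), dtype=np.int64)
    elif scenario.population_model == "lognormal":
        # sigma=1 lognormal scaled to the requested mean, Poisson-rounded
        lam = rng.lognormal(mean=0.0, sigma=1.0, size=shape)
        lam *= mean / np.exp(0.5)
        counts = rng.poisson(lam).astype(np.int64)
    else:  # cities: a few gaussian bumps over a thin rural background
        n_cities = max(3, (scenario.n_cols * scenario.n_rows) // 800)
        cx = rng.uniform(0, scenario.n_cols, n_cities)
        cy = rng.uniform(0, scenario.n_rows, n_cities)
        sigma = rng.uniform(1.5, 5.0, n_cities)
        yy, xx = np.mgrid[0 : scenario.n_rows, 0 : scenario.n_cols]
        lam = np.full(shape, 0.1 * mean)
        for x, y, s in zip(cx, cy, sigma):
            lam += (
                10.0 * mean * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s * s))
            )
        lam *= mean / lam.mean()
        counts = rng.poisson(lam).astype(np.int64)
    return CountGrid(spec=scenario.spec, counts=counts, label="population")


def _place_individuals(
    pop_grid: CountGrid, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n individual locations (easting, northing) ∝ cell population,
    uniform within the cell; returns planar coordinates."""
    spec = pop_grid.spec
    rows, cols = np.nonzero(pop_grid.counts)
    w = pop_grid.counts[rows, cols].astype(float)
    w /= w.sum()
    idx = rng.choice(rows.size, size=n, p=w)
    u = rng.uniform(0.0, 1.0, size=(n, 2))
    east = (cols[idx] + spec.col_range[0] + u[:, 0]) * spec.resolution_m
    north = (rows[idx] + spec.row_range[0] + u[:, 1]) * spec.resolution_m
    return east, north


def simulate_case_control(
    scenario: SimScenario,
    pop_grid: CountGrid,
    cohort_size: int | None = None,
    entities: Mapping[str, EnvEntity] | None = None,
    classes: Mapping[str, EntityClass] | None = None,
    thresholds: ExposureThresholds | None = None,
) -> tuple[list[PointRecord], list[PointRecord]]:
    """Sample a cohort and split it into cases and controls.

    Individuals are placed proportionally to population.  Each is a case
    with probability p₀, multiplied by the planted relative risk inside the
    planted zone.  If the scenario plants a proximity effect and the entity
    tables are supplied, the case *odds* are additionally multiplied by the
    planted per-band odds ratio of the affected class, which induces that
    odds-ratio profile in the downstream exposure analysis.
    """
    rng = scenario.rng("cases")
    if cohort_size is None:
        cohort_size = int(pop_grid.total)
    east, north = _place_individuals(pop_grid, cohort_size, rng)

    p0 = scenario.baseline_rate
    odds = np.full(cohort_size, p0 / (1.0 - p0))
    if scenario.planted_cluster is not None:
        zone, rr = scenario.planted_cluster
        res = scenario.resolution_m
        inside = (
            (east >= zone.col_min * res)
            & (east < (zone.col_max + 1) * res)
            & (north >= zone.row_min * res)
            & (north < (zone.row_max + 1) * res)
        )
        p_in = np.minimum(p0 * rr, 0.999)
        odds[inside] = p_in / (1.0 - p_in)
    if scenario.planted_effect is not None and entities and thresholds is not None:
        class_id, or_by_band = scenario.planted_effect
        members = [entities[eid] for eid in sorted(classes[class_id].members)]
        coords = np.array([(e.easting, e.northing) for e in members])
        d2 = (
            (east[:, None] - coords[None, :, 0]) ** 2
            + (north[:, None] - coords[None, :, 1]) ** 2
        )
        dist = np.sqrt(d2.min(axis=1))
        band = assign_exposure(dist, thresholds)
        for lv, or_target in or_by_band.items():
            odds[band == lv] *= or_target

    p_case = odds / (1.0 + odds)
    is_case = rng.uniform(size=cohort_size) < p_case
    if not np.any(is_case):
        raise ValueError("simulation produced no cases; raise baseline_rate or cohort size")

    cases = [
        PointRecord(id=f"case{i}", group="case", easting=float(east[i]), northing=float(north[i]))
        for i in np.nonzero(is_case)[0]
    ]
    controls = [
        PointRecord(id=f"ctrl{i}", group="control", easting=float(east[i]), northing=float(north[i]))
        for i in np.nonzero(~is_case)[0]
    ]
    return cases, controls


def simulate_entities(
    scenario: SimScenario,
) -> tuple[dict[str, EnvEntity], dict[str, EntityClass]]:
    """Scatter environmental entities uniformly and group them into classes.

    Entities are assigned to classes at random; an entity may belong to
    several classes.  The planted-effect class id (if any) is guaranteed to
    exist and be non-empty.
    """
    rng = scenario.rng("entities")
    spec = scenario.spec
    res = scenario.resolution_m
    entities: dict[str, EnvEntity] = {}
    if scenario.n_entities == 0:
        return {}, {}
    east = rng.uniform(spec.col_range[0] * res, (spec.col_range[1] + 1) * res, scenario.n_entities)
    north = rng.uniform(spec.row_range[0] * res, (spec.row_range[1] + 1) * res, scenario.n_entities)
    for i in range(scenario.n_entities):
        eid = f"e{i}"
        entities[eid] = EnvEntity(entity_id=eid, easting=float(east[i]), northing=float(north[i]))

    class_ids = [f"class{k}" for k in range(scenario.n_classes)]
    if scenario.planted_effect is not None:
        planted_id = scenario.planted_effect[0]
        if planted_id not in class_ids:
            class_ids.append(planted_id)
    members: dict[str, set[str]] = {cid: set() for cid in class_ids}
    for eid in entities:
        k = rng.integers(0, len(class_ids))
        members[class_ids[k]].add(eid)
        if rng.uniform() < 0.2:  # multi-class membership
            k2 = rng.integers(0, len(class_ids))
            members[class_ids[k2]].add(eid)
    # ensure no analyzed class is empty
    for cid in class_ids:
        if not members[cid]:
            members[cid].add(rng.choice(sorted(entities)))
    classes = {
        cid: EntityClass(class_id=cid, members=frozenset(members[cid])) for cid in class_ids
    }
    return entities, classes
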