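# Methods

## Grid model

All analyses run on a square grid aligned with the ETRS89-LAEA plane
(EPSG:3035: Lambert Azimuthal Equal-Area on GRS80, centre 10°E 52°N, false
easting 4 321 000 m, false northing 3 210 000 m).  The projection is
authalic, so a cell of side `r` covers exactly `r²` of ground area anywhere
on the map — per-cell counts are therefore directly comparable, which is
the property that justifies count-based statistics on the grid.  The
forward and inverse transforms are implemented from the classical
ellipsoidal formulas (Snyder's *Map Projections — A Working Manual*); they
reproduce the published EPSG worked example (50°N 5°E → E 3 962 799.45 m,
N 2 999 718.85 m) to centimetres and round-trip to below 1e-9°.

Cell indexing is `(col, row) = (⌊E/r⌋, ⌊N/r⌋)` with half-open cells: a
point exactly on an upper edge belongs to the next cell.  With the default
1 km resolution this makes grid coordinate 3610 the cell whose lower-left
corner is at easting 3 610 000 m, matching the Eurostat GEOSTAT convention
(`1kmN<row>E<col>` identifiers, which the population-grid reader parses).
Zone corners in reports are cell-corner coordinates (multiples of the
resolution), not cell centres.  Points that fall outside the configured
grid are collected in a rejects list with reasons and reported in the run
log, never silently dropped.

Count grids are transformed once into zero-padded summed-area tables
(integral images); the count in any rectangle then costs exactly four array
reads.  The `PrefixGrid.reads` counter instruments this so the
constant-cost-per-window claim is asserted structurally (≤ 8 reads per
window across the two grids) rather than by wall-clock measurement.

## Cluster scan

The scan statistic is the numerator of Kulldorff's binomial likelihood
ratio.  With `c` cases among `n` individuals in the zone and `C` of `N`
overall, and `p̂ = c/n`, `q̂ = (C−c)/(N−n)`:

* if `p̂ > q̂` the supremum over `p > q` of the likelihood is attained at
  `(p̂, q̂)` and the log numerator is
  `c ln p̂ + (n−c) ln(1−p̂) + (C−c) ln q̂ + (N−n−C+c) ln(1−q̂)`;
* otherwise the supremum sits on the boundary `p = q` and equals the pooled
  null value `C ln(C/N) + (N−C) ln(1−C/N)`, so a zone with a case deficit
  is never rewarded.

Terms with a zero count contribute zero (`0·ln 0 ≡ 0`, computed with
`xlogy`); everything is evaluated in log space.  The implementation is
checked against an independent oracle that maximises the likelihood
numerically over a fine `(p, q)` lattice restricted to `p ≥ q` (the
supremum over the open region equals the maximum over its closure by
continuity).

Windows are axis-aligned rectangles; the default size set is all widths ×
heights in 1..10 cells, moved at 1-cell steps.  Zones are capped at half
the study population (`max_zone_fraction = 0.5`), the usual "zone smaller
than its complement" convention.  If the cap is raised to 1 a window may
cover all N individuals; its score is then exactly the null value (the
formula degrades continuously), so such a window can be enumerated but can
never rank above a genuine excess.  Ties are broken deterministically:
smaller area first, then lower-left position, then shape.  When a
population grid stands in for controls, the population count (minus the
cases) plays the role of the control count, so `n` is zone population and
`N` total population.

### Monte-Carlo inference

The source method ranks zones by the statistic alone; p-values here are a
standard addition.  The null fixes every individual's location and the
case total `C`, and permutes which individuals are cases — per-cell case
counts under one permutation are a multivariate hypergeometric draw from
the per-cell totals.  For each of `R` permutations the best statistic over
*all* windows is recorded (the same maximisation applied to the data), and
`p = (1 + #{best ≥ observed}) / (1 + R)`.  Permutation grids are processed
as one batched 3-D summed-area table, so 999 permutations of a small grid
cost milliseconds.  A single seeded generator drives all permutations;
results are bit-reproducible from `(seed, n_permutations)`.

## Exposure analysis

Exposure is assigned per cell: every individual inherits the level of their
cell, determined by the Euclidean distance in the projected plane from the
cell centre to the nearest entity of the class (a KD-tree query, verified
against brute force).  This is faithful to the grid philosophy and bounds
the positional error by the half-cell diagonal (~707 m at 1 km); plane
distances differ from ellipsoidal ones by far less than that over band
radii of a few tens of km.  Bands are closed on the near side: a distance
exactly at `r_H` is High, beyond `r_L` is Unexposed.  Only the nearest
entity matters — presence, not counts or emission quantities, defines
exposure; counting entities per band would be an alternative dose proxy but
is not implemented.

Each exposed level is compared with the unexposed stratum in its own 2×2
table (individuals at other levels are excluded from that table).  The odds
ratio uses the Woolf log-method CI, `exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d))`;
any zero cell triggers the Haldane–Anscombe +0.5 correction on all four
cells and flags the result; an all-zero row yields a flagged NaN rather
than an exception, so one degenerate class cannot abort a 160-class run.

The dose–response ("tendency") test is Cochran–Armitage with equally
spaced scores U=0, L=1, M=2, H=3, using the hypergeometric (permutation)
variance with its `N/(N−1)` factor, two-sided normal p.  A logistic
regression on the level index would be the model-based alternative; the
categorical trend test was chosen because it needs no link assumption and
matches the permutation oracle it is tested against.  Classes are tested
one at a time — high per-test power, classical multiplicity burden — so
trend p-values are corrected across classes: Bonferroni by default,
Benjamini–Hochberg as an option.  An optional `[from, to]` year filter on
the entity–class link table restricts membership to emissions in a span.

## Virtual controls

Density matching uses population-per-cell quantile bins (deciles by
default) over inhabited cells: the case distribution over bins defines the
sampling weights; each control draws a bin, then a cell within the bin with
probability proportional to its population, then a uniform position inside
the cell (controls are grid-resolution objects, so sub-cell placement
carries no information).  Nearest-density cell matching would be a
non-binned alternative; quantile bins were preferred because they make the
match diagnosable with a simple goodness-of-fit count.  Each series has its
own RNG stream derived from `(seed, series_id)`, so series are individually
reproducible.  Aggregation across series reports per class and level the
median OR, the 2.5/97.5 percentiles, and the fraction of series significant
after correction.

## Synthetic scenarios

`synthetic_fixtures` emulates: a population surface (uniform, lognormal, or
a few-cities mixture of Gaussian bumps on a thin background), a cohort
placed proportionally to population with per-individual case probability
`p₀` (multiplied by the planted relative risk inside a planted rectangle),
and uniformly scattered entity classes.  A planted proximity effect
multiplies each individual's case *odds* by the target per-band odds ratio
of the affected class at case-assignment time — this induces the target OR
profile directly and exactly, rather than approximating it by resampling
case locations toward entities.  One RNG per scenario is split into named
substreams (population / cases / entities), so extending one generator
never perturbs the draws of another.

What the fixtures do **not** emulate: real geography (regions are abstract
rectangles near the projection origin), spatially autocorrelated risk
other than the single planted rectangle, within-household clustering,
covariates (age/sex), or geocoding error.  Passing tests therefore show the
algorithms are correct under the stated sampling models, not that any
particular real dataset would yield signal.

## Problem sizes and numerical choices

* Statistic-vs-lattice agreement is checked at 1e-6 relative tolerance over
  500 random count configurations; the lattice is a 4001-point uniform grid
  augmented with the three stationary probabilities.
* Planted-cluster recovery uses 100 replicates of a 100×100 grid (lognormal
  surface, cohort 100 000, p₀ = 0.01, 5×5 zone at RR 10) and requires the
  top candidate to overlap the planted zone in ≥ 95 of them.
* Monte-Carlo calibration uses 500 replicates of a homogeneous 15×15 null
  (per-cell totals Poisson(2), 10% cases, 999 permutations each) and
  requires the rejection rate at α = 0.05 to lie in [0.03, 0.07].
* Exposure recovery plants OR (H, M, L) = (3, 2, 1.5) in a cohort of 5000
  and requires each target inside its 95% CI.
* Degenerate inputs: empty point lists yield zero grids; a scan with no
  cases raises; an entity class with no located entities is skipped with a
  recorded reason; trend tables with an empty case or control row return
  (0, 1).

## Known limitations

Windows are rectangles only (no circles or ellipses, no space–time scan).
Only the WGS84 ↔ EPSG:3035 transform is built in; other grids require
pre-projected planar coordinates.  Continuous exposure fields (temperature,
atmospheric concentrations) are out of scope by design — the exposure model
requires factors that are present or absent at points.  Monte-Carlo
p-values are conditional on the observed case total and locations;
covariate adjustment is not provided.
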