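# Methods

This note records the models the package implements, the conventions that
published definitions leave open, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate.

## Data model and conventions

Rasters are 2-D integer (categorical) or float (driver) arrays with square
cells, north-up, row-major, cell (0, 0) at the upper-left corner.  Areas are
hectares throughout (`cell_size² / 10 000`).  Nodata cells are excluded from
every count, metric, and allocation and never convert.  Georeference is
treated as opaque: the package enforces alignment (shape, cell size, origin
within 1e-6 cell) but performs no reprojection.  ESRI ASCII grid is the
canonical interchange format; single-band GeoTIFF is read/written through
tifffile with ModelPixelScale/ModelTiepoint/GDAL_NODATA tags.

The six-class scheme (farmland 1, forest 2, built-up 3, water 4, aquaculture
5, other 6) carries ordinal vulnerability grades: built-up 1 (intensively
managed, most stable), forest 2, farmland 3, aquaculture 4, water 5, other
open land 6 (least managed, most fragile).

## Change accounting

`cross_tabulate` counts cells per ordered class pair between two dates;
cells that are nodata at either date are dropped from both marginals so the
grand total is constant across dates.  The dynamic degree index is the
off-diagonal share of total area × 100; its denominator is the whole
landscape area at the start date (the aggregate usage; a per-class variant
is exposed separately).  Rows of the probability matrix for classes absent
at the start date default to self-transition.

The published class-area table and both transition matrices ship as CSV
package data.  The 2004–2013 matrix's printed net-gain/loss row is
internally inconsistent with its own matrix (e.g. farmland −7901.55 printed
vs −9909.81 = column − row sum); the matrix is treated as authoritative and
the printed row of that table is not asserted anywhere.

## Landscape metrics

Definitions follow the standard raster formulations; the conventions below
matter numerically and are fixed as:

- **Patches**: 8-connected components per class (configurable to 4).
  Perimeter counts cell edges adjoining a different class, nodata, or the
  grid boundary, × cell size.
- **CONTAG**: 4-neighbor adjacencies, double-counted (each internal edge
  seen from both sides), like-adjacencies included, nodata edges excluded;
  `CONTAG = [1 + Σ q ln q / (2 ln m)] × 100` with `q_ik = P_i g_ik / Σ_k
  g_ik` and m the number of classes present.  Note a two-class
  equal-composition checkerboard concentrates adjacency mass on the two
  unlike pairs (entropy ln 2) and therefore scores *higher* than solid
  blocks; the low-contagion extreme is the *random* (uniform-adjacency)
  pattern, and tests assert exactly that comparison plus the monotone trend
  of the two-block landscape as the interface/area ratio shrinks (limit 50
  at equal shares; 100 requires a single class to dominate).
- **SPLIT**: `A²/Σ a_j²` with A the total landscape (or zone) area, also for
  class-level values.
- **PAFRAC**: `2 / b`, b the OLS slope of ln(area) regressed on
  ln(perimeter) across patches.  The regression direction is fixed because
  OLS is not symmetric; fewer than two patches or zero perimeter variance
  yields an undefined flag, and values outside [1, 2] are reported with the
  flag rather than clipped.
- **Zonal metrics** delineate patches inside the zone mask only (patches
  truncate at zone borders) and use the zone's valid extent as A, so each
  town is evaluated as its own landscape.

## Ecological risk

`R = Σ_i α_i √(D_i V_i)` per zone, with α the class area share inside the
zone, `D_i = w₁·SPLIT′_i + w₂·PD′_i + w₃·SHDI′` (defaults 0.3/0.5/0.2), and
SHDI′ the zone-level value shared by every class of the zone (the diversity
term carries no class subscript).  Metrics are min–max normalized across the
full cohort of (zone, class, date) observations passed in one call — the
joint cohort keeps risk values comparable across dates, which the temporal
comparison requires; a per-date mode is available.  A constant metric
normalizes to 0 with a warning (no relative disturbance signal).
Vulnerability defaults to grade/Σgrades (grades 1..6 → /21), which keeps
every class's V strictly positive; min–max normalization (which zeroes the
built-up class out of the risk sum) is selectable.  Since D, V, α ∈ [0, 1]
and Σα = 1, R ∈ [0, 1]; categories are right-closed 0.2-wide bands, with 0
in the lowest band.

## LSSVM transition rules

For each ordered pair (i → j) observed in the calibration interval,
positives are cells with (t1 = i, t2 = j) and negatives same-source
unconverted cells (t1 = i, t2 ≠ j), balanced 1:1, up to 500 per side, drawn
without replacement under an explicit seed; shortfalls take all occurrences
and warn.  Training solves the dual system
`[[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y]` with RBF kernel on features
standardized by training-set statistics; the KKT residual is recorded on the
model (observed ≲ 1e-11; tests require < 1e-8).  Persistence pairs (i → i)
are trained for completeness, but persistence is handled residually by the
allocator.

Defaults: γ = 10; σ = √(d/2) for d features — the dimension-scaled width
equivalent to the common `exp(−‖Δx‖²/d)` kernel.  A fixed σ = 1 in 8
standardized dimensions puts typical kernel values near exp(−8), which
degenerates toward a diagonal (memorizing) kernel and measurably degrades
suitability recovery; the dimension-scaled default restores it.  Both remain
overridable.

Decision values on the current source-class cells are min–max mapped to
[0, 1] (constant surfaces map to 0.5; a logistic squash is available);
non-source cells are 0, and untrained transitions fall back to an all-zero
surface.

## Markov-CA allocation

Demands: off-diagonal matrix areas are rounded to whole cells and split
equally over the iterations, remainders to the earliest iterations
(largest-remainder rule), so scheduled totals equal the rounded targets
exactly.  The default 18 iterations represent half-year steps over a
nine-year calibration window.

Each iteration, candidates for (i → j) are current class-i cells not under
an immutable mask; their score is `suitability(i→j) × (ε + neighborhood
fraction of j)` with a 3×3 window (truncated at borders, center excluded)
and contiguity floor ε = 0.1, which keeps isolated but highly suitable cells
eligible.  The top-demand cells convert; a cell claimed by several pairs
goes to its highest-scoring claim; ties break by a seeded uniform jitter
(~1e-12), making runs bit-reproducible under a fixed seed.  Unmet demand
rolls to the next iteration and any residue after the last iteration is
reported, never force-allocated.  Validation compares simulated and observed
maps by percent correct and Cohen's kappa from the cell-level confusion
matrix.

## Scenarios

S1 is an empty spec (verified equal to a plain simulation).  S2 makes the
permanent-farmland mask immutable and floors farmland at its start-year
area.  S3 multiplies suitability of all transitions into forest and water by
1.2 inside grade-1 conservation zones and 1.1 inside grade-2 (clipped at 1)
and floors forest and water at start-year areas.  S4 multiplies suitability
into built-up by 1.2 everywhere ("development probability 20% higher" read
as a suitability boost, consistent with the S3 wording).  Floors are
enforced ex-ante each iteration by pro-rata capping of the floored class's
out-demands (largest-remainder rounding), so they hold at every iteration,
not just at snapshots.

Projection runs on half-year steps from the 2013 analog; snapshot years
2015/2020/2025/2030 are iterations 4/14/24/34.  Demands beyond the 18-step
calibration cycle reapply the per-iteration schedule cyclically: linear
rescaling of the nine-year matrix by 34/18 is infeasible (it drives
low-persistence classes to negative diagonals), while cycling keeps every
iteration at the calibrated conversion intensity.

A caveat on boost monotonicity: raising a class's suitability multipliers
weakly increases its conflict wins within an iteration (strictly provable
when no value clips at 1), but clipping creates score ties whose resolution
can change claim sets, and any change cascades through later iterations.
Measured S4-vs-S1 built-up deficits are ≈0.1–0.2% at the 2030 horizon;
dominance is therefore asserted up to a 0.5% allocation-granularity
tolerance, while floors and immutability hold exactly and are asserted
exactly.

## Synthetic world

The generator emulates the statistical structure the pipeline assumes, at
desk scale: 150×150 cells of 100 m (2250 ha), six classes at the region's
2004 area proportions, nine Voronoi zones.  Landscapes are argmax-of-latent
Gaussian fields smoothed at an autocorrelation length of 6 cells, with class
offsets calibrated iteratively so empirical shares track the target within
~3 percentage points.  Drivers are exact Euclidean distance transforms of
random line features (highway, railway, 3 roads) and point features (8 town
centers, 2 urban centers), distance to the largest connected water body, a
multi-octave smoothed-noise DEM (80 m relief), and its Horn slope.

The ground-truth transition process is multinomial-logit per cell:
`P(j | i, x) = softmax(base_ij + β_jᵀx + η·f_j)` with x the standardized
drivers and f_j the 3×3 neighborhood fraction of class j.  Defaults, chosen
once: base log-odds are the log of the observed 2004–2013 transition
frequencies, so one synthetic step carries the study region's nine-year
change intensity; driver couplings are development toward roads and urban
centers (−2.0, −1.5), aquaculture toward water (−2.0), forest uphill (+1.5),
farmland downhill (−0.8), and η = 1.0.  The driver terms dominate the
neighborhood term by design: the generator exists to test whether
driver-based suitability learning recovers the true probability ordering,
which requires the recoverable (driver) signal to carry most of the
between-cell variance.  The generator returns the exact per-cell probability
surfaces beside each realization so stochastic tests can use closed-form
expectations.

What passing synthetic tests shows — and does not: they verify the
machinery (metric formulas against brute-force oracles, conservation,
determinism, recovery of a known monotone driver dependence, constraint
enforcement) under a world whose drivers really do generate the conversions.
They do not validate the risk index or the simulator against the real
region's geography: the published configuration-metric values (CONTAG/
SPLIT/PD/PAFRAC), the 67%/0.53 validation figures, and the town-level risk
means require the original rasters, which are not publicly deposited.
Composition-only quantities (SHDI and all transition-matrix statistics) are
reproduced from the printed tables to printed precision.

## Numerical choices and degenerate inputs

- Min–max normalization of a constant collection → all zeros plus a warning.
- Transition-probability rows for absent classes → self-transition.
- PAFRAC with < 2 patches or zero ln-perimeter variance → flagged undefined.
- CONTAG on a single-class landscape → error (division by ln 1).
- Empty zones → flagged undefined risk rows, never silent NaNs.
- Demand rounding uses rint; feasibility (out-demand ≤ source cells) is
  checked per class with the offending pair named.
- All stochastic steps (sampling, jitter, generators) consume explicit
  numpy Generator seeds; problem sizes in tests (60×60 worlds for pipeline
  units, 150×150 for the end-to-end and recovery checks, 200 random ≤30×30
  grids for the metric oracles) were chosen to exercise every code path at
  desk scale.

## Known limitations

- The allocator is a documented stand-in for proprietary CA-Markov
  implementations: contiguity filtering and multi-objective conflict
  resolution are specified here (multiplicative score, highest-claim-wins,
  roll-forward) rather than reverse-engineered.
- No vector GIS, reprojection, or cartography; inputs must be pre-aligned.
- Markov demands are one-step (no ergodic/stationary analysis), and
  long-horizon projections assume calibrated per-iteration intensities
  persist.
- LSSVM training is dense (O(n³) in samples); fine at 1000 samples per
  model, unsuitable for orders of magnitude more without low-rank methods.
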