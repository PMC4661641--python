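"""Markov-constrained cellular-automata land-change simulation.

The Markov side fixes *how much* land converts: the calibrated area
transition matrix is turned into integer per-iteration cell demands (equal
apportionment with largest-remainder rounding, remainders to the earliest
iterations).  The CA side decides *where*: for each demanded pair (i -> j),
candidate source cells are ranked by suitability multiplied by a
neighborhood contiguity factor (fraction of window neighbors already in the
target class, floored at epsilon so isolated but suitable cells stay
eligible), and the top-demand cells convert.  A cell claimed by several
pairs goes to its highest-scoring claim; unmet demand rolls forward and any
residue after the last iteration is reported, never force-allocated.

Also provides map-agreement validation: percent correct and Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .change import TransitionMatrix
from .grid import LandCoverGrid
from .lssvm import SuitabilityStack

__all__ = [
    "SimulationConfig",
    "demand_schedule",
    "neighborhood_factor",
    "allocate_iteration",
    "cap_demands_to_floors",
    "simulate",
    "SimulationReport",
    "overall_accuracy",
    "kappa_coefficient",
    "confusion_matrix",
]


@dataclass
class SimulationConfig:
    """Knobs of one simulation run.

    iterations: number of CA steps (18 half-year steps covers the nine-year
    calibration window).  window: odd neighborhood size (3 = the 8 cells
    around a cell).  eps: contiguity floor in (0, 1].  immutable_mask: cells
    barred from any conversion.  class_area_floors: minimum hectares per
    class code, enforced by capping out-demands every iteration.
    """

    iterations: int = 18
    window: int = 3
    seed: int = 0
    eps: float = 0.1
    immutable_mask: np.ndarray | None = None
    class_area_floors: dict[int, float] = field(default_factory=dict)
    suitability_multipliers: list = field(default_factory=list)  # set via scenarios

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.window % 2 != 1:
            raise ValueError("neighborhood window must be odd")
        if not 0 < self.eps <= 1:
            raise ValueError("eps must lie in (0, 1]")


def demand_schedule(
    tm: TransitionMatrix, iterations: int, cell_area_ha: float
) -> np.ndarray:
    """Integer per-iteration conversion demands, shape (iterations, n, n).

    Off-diagonal areas are rounded to whole cells and split equally across
    iterations; remainders go to the earliest iterations so the per-pair sum
    over iterations equals the rounded target exactly.
    """
    if cell_area_ha <= 0:
        raise ValueError("cell_area_ha must be positive")
    n = tm.scheme.n_classes
    counts = np.rint(tm.area / cell_area_ha).astype(np.int64)
    row_cells = np.rint(tm.row_sums() / cell_area_ha).astype(np.int64)
    sched = np.zeros((iterations, n, n), dtype=np.int64)
    for i in range(n):
        out_total = counts[i].sum() - counts[i, i]
        if out_total > row_cells[i]:
            pair = np.argmax(np.where(np.arange(n) != i, counts[i], -1))
            raise ValueError(
                f"demand from class {tm.scheme.codes[i]} ({out_total} cells, e.g. pair "
                f"{tm.scheme.codes[i]}->{tm.scheme.codes[int(pair)]}) exceeds its "
                f"{row_cells[i]} available cells"
            )
        for j in range(n):
            if i == j or counts[i, j] == 0:
                continue
            base, rem = divmod(int(counts[i, j]), iterations)
            sched[:, i, j] = base
            sched[:rem, i, j] += 1
    return sched


def neighborhood_factor(
    grid: LandCoverGrid, target_class: int, window: int = 3
) -> np.ndarray:
    """Per cell: fraction of in-window, non-center, non-nodata neighbors in the target class.

    Windows truncate at the grid border; cells with no valid neighbors get 0.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    is_target = ((grid.values == target_class) & grid.valid_mask).astype(float)
    valid = grid.valid_mask.astype(float)
    kernel = np.ones((window, window))
    tgt = ndimage.convolve(is_target, kernel, mode="constant", cval=0.0)
    cnt = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    tgt -= is_target  # remove center cell
    cnt -= valid
    out = np.zeros(grid.shape)
    np.divide(tgt, cnt, out=out, where=cnt > 0)
    return np.clip(out, 0.0, 1.0)


def _pair_scores(
    state: LandCoverGrid,
    suit: SuitabilityStack,
    neigh: dict[int, np.ndarray],
    i: int,
    j: int,
    eps: float,
) -> np.ndarray:
    return suit.get(i, j) * (eps + neigh[j])


def allocate_iteration(
    state: LandCoverGrid,
    suit: SuitabilityStack,
    demands: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[LandCoverGrid, np.ndarray]:
    """One CA step: convert the demanded number of cells per pair.

    Returns (next state, shortfall counts per pair).  Processing is in fixed
    class-pair order; ties in score are broken by a seeded uniform jitter so
    runs are deterministic under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    codes = state.scheme.codes
    n = len(codes)
    valid = state.valid_mask
    immutable = (
        config.immutable_mask
        if config.immutable_mask is not None
        else np.zeros(state.shape, dtype=bool)
    )
    neigh = {
        j_code: neighborhood_factor(state, j_code, config.window) for j_code in codes
    }
    best_score = np.full(state.shape, -np.inf)
    best_target = np.full(state.shape, -1, dtype=np.int64)  # class index
    claimed = np.zeros((n, n), dtype=np.int64)
    jitter_scale = 1e-12
    for ii, i_code in enumerate(codes):
        src = (state.values == i_code) & valid & ~immutable
        if not src.any():
            continue
        rows, cols = np.nonzero(src)
        for jj, j_code in enumerate(codes):
            d = int(demands[ii, jj])
            if ii == jj or d == 0:
                continue
            score = _pair_scores(state, suit, neigh, i_code, j_code, config.eps)
            s = score[rows, cols] + rng.uniform(0, jitter_scale, size=len(rows))
            k = min(d, len(s))
            if k == 0:
                continue
            top = np.argpartition(-s, k - 1)[:k]
            claimed[ii, jj] = k
            r, c = rows[top], cols[top]
            win = s[top] > best_score[r, c]
            best_score[r[win], c[win]] = s[top][win]
            best_target[r[win], c[win]] = jj
    next_values = state.values.copy()
    converted = np.zeros((n, n), dtype=np.int64)
    conv_mask = best_target >= 0
    if conv_mask.any():
        rows, cols = np.nonzero(conv_mask)
        lut = np.full(max(codes) + 1, -1, dtype=np.int64)
        for k_idx, c in enumerate(codes):
            lut[c] = k_idx
        src_idx = lut[state.values[rows, cols]]
        tgt_idx = best_target[rows, cols]
        next_values[rows, cols] = np.asarray(codes)[tgt_idx]
        np.add.at(converted, (src_idx, tgt_idx), 1)
    shortfall = demands - converted
    np.fill_diagonal(shortfall, 0)
    next_state = LandCoverGrid(
        next_values, state.cell_size, state.origin, state.nodata, state.scheme
    )
    return next_state, shortfall


def cap_demands_to_floors(
    state: LandCoverGrid,
    demands: np.ndarray,
    floors: dict[int, float],
) -> np.ndarray:
    """Cap out-demands so no floored class can drop below its minimum area.

    The allowable total out-flow of a floored class is its current excess
    over the floor (in cells); out-demands are scaled pro-rata with
    largest-remainder rounding.  Raises on floors above the current area.
    """
    if not floors:
        return demands
    codes = state.scheme.codes
    capped = demands.copy()
    cell_area = state.cell_area_ha
    areas = state.class_areas_ha()
    for code, floor in floors.items():
        ii = state.scheme.index_of(code)
        if floor > areas[code] + 0.5 * cell_area:
            raise ValueError(
                f"floor {floor} ha for class {code} exceeds current area {areas[code]} ha"
            )
        headroom = max(0, int(np.floor((areas[code] - floor) / cell_area + 1e-9)))
        out = capped[ii].copy()
        out[ii] = 0
        total = int(out.sum())
        if total <= headroom:
            continue
        if headroom == 0:
            capped[ii] = np.where(np.arange(len(codes)) == ii, capped[ii], 0)
            continue
        scaled = out * headroom / total
        base = np.floor(scaled).astype(np.int64)
        rem = scaled - base
        deficit = headroom - int(base.sum())
        order = np.argsort(-rem, kind="stable")
        base[order[:deficit]] += 1
        for jj in range(len(codes)):
            if jj != ii:
                capped[ii, jj] = base[jj]
    return capped


@dataclass
class SimulationReport:
    """Per-run accounting: demands met, shortfalls, class totals per iteration."""

    class_counts: list[dict[int, int]]
    shortfall_total: np.ndarray
    capped_total: np.ndarray
    projected_counts: dict[int, float]


def simulate(
    initial: LandCoverGrid,
    tm: TransitionMatrix,
    suit: SuitabilityStack,
    config: SimulationConfig,
    snapshots: list[int] | None = None,
    schedule: np.ndarray | None = None,
) -> tuple[list[LandCoverGrid], SimulationReport]:
    """Run the Markov-CA for ``config.iterations`` steps from ``initial``.

    Returns the state sequence (initial state first; all iterations, or only
    the requested 1-based snapshot iterations plus the initial state) and a
    report.  ``schedule`` overrides the per-iteration demands (must have
    ``config.iterations`` leading entries); by default demands come from
    ``demand_schedule`` on ``tm``.  The Markov projection for the final
    state is the column total of the scheduled demands.
    """
    n = initial.scheme.n_classes
    if schedule is None:
        sched = demand_schedule(tm, config.iterations, initial.cell_area_ha)
    else:
        if schedule.shape[0] < config.iterations:
            raise ValueError("schedule shorter than the configured iterations")
        sched = schedule[: config.iterations]
    rng = np.random.default_rng(config.seed)
    state = initial.copy()
    states = [state]
    carry = np.zeros((n, n), dtype=np.int64)
    shortfall_total = np.zeros((n, n), dtype=np.int64)
    capped_total = np.zeros((n, n), dtype=np.int64)
    counts_log = [state.class_areas_ha()]
    for t in range(config.iterations):
        demands = sched[t] + carry
        if config.class_area_floors:
            before = demands.copy()
            demands = cap_demands_to_floors(state, demands, config.class_area_floors)
            capped_total += before - demands
        state, shortfall = allocate_iteration(state, suit, demands, config, rng)
        carry = shortfall
        counts_log.append(state.class_areas_ha())
        if snapshots is None or (t + 1) in snapshots:
            states.append(state)
    shortfall_total = carry
    # Markov projection of final class cell counts from the demand totals.
    counts0 = {
        c: int(np.count_nonzero(initial.values == c)) for c in initial.scheme.codes
    }
    total_demands = sched.sum(axis=0)
    projected = {}
    for k, c in enumerate(initial.scheme.codes):
        out_d = int(total_demands[k].sum() - total_demands[k, k])
        in_d = int(total_demands[:, k].sum() - total_demands[k, k])
        projected[c] = float(counts0[c] - out_d + in_d)
    report = SimulationReport(
        class_counts=counts_log,
        shortfall_total=shortfall_total,
        capped_total=capped_total,
        projected_counts=projected,
    )
    return states, report


# ---------------------------------------------------------------------------
# Map-agreement validation
# ---------------------------------------------------------------------------

def confusion_matrix(simulated: LandCoverGrid, observed: LandCoverGrid) -> np.ndarray:
    """Cell-level confusion counts, simulated in rows, observed in columns."""
    if simulated.shape != observed.shape:
        raise ValueError("maps must share shape")
    valid = simulated.valid_mask & observed.valid_mask
    if not valid.any():
        raise ValueError("no overlapping valid cells")
    codes = simulated.scheme.codes
    lut = np.full(max(codes) + 1, -1, dtype=np.int64)
    for k, c in enumerate(codes):
        lut[c] = k
    i = lut[simulated.values[valid]]
    j = lut[observed.values[valid]]
    n = len(codes)
    return np.bincount(i * n + j, minlength=n * n).reshape(n, n)


def overall_accuracy(simulated: LandCoverGrid, observed: LandCoverGrid) -> float:
    """Fraction of matching non-nodata cells (percent correct / 100)."""
    cm = confusion_matrix(simulated, observed)
    return float(np.trace(cm) / cm.sum())


def kappa_coefficient(simulated: LandCoverGrid, observed: LandCoverGrid) -> float:
    """Cohen's kappa from the cell-level confusion matrix."""
    cm = confusion_matrix(simulated, observed).astype(float)
    total = cm.sum()
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum() / total**2)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: expected agreement is 1 but maps differ")
    return float((p_o - p_e) / (1 - p_e))
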