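"""Policy scenarios as constraint/boost transformations on the simulator.

Four scenarios probe land policy to 2030 from a 2013 start:

* S1 — status quo: the calibrated drivers and demands run unchanged.
* S2 — farmland protection: planned permanent farmland is immutable and the
  farmland total never drops below its 2013 area.
* S3 — ecological conservation: suitability of transitions into forest and
  water is boosted by 20% inside first-grade conservation zones and 10%
  inside second-grade zones (clipped at 1), with forest and water floors at
  their 2013 areas.
* S4 — urban development: suitability of every transition into built-up is
  raised 20% everywhere (clipped at 1).

Projection runs on half-year steps from 2013, so snapshot years 2015 / 2020 /
2025 / 2030 fall on iterations 4 / 14 / 24 / 34.  Demands extend the
calibrated 2004-2013 transition matrix by reapplying its 18-step
per-iteration demand schedule cyclically over the longer horizon, keeping
every iteration at the calibrated conversion intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ca import SimulationConfig, cap_demands_to_floors, simulate
from .change import TransitionMatrix
from .grid import LandCoverGrid, ZoneGrid
from .lssvm import SuitabilityStack
from .risk import DisturbanceWeights, zonal_risk

__all__ = [
    "ScenarioSpec",
    "build_scenario",
    "apply_scenario",
    "enforce_floors",
    "run_projection",
    "SNAPSHOT_ITERATIONS",
]

#: Half-year iterations from 2013 at which snapshots are emitted.
SNAPSHOT_ITERATIONS = {2015: 4, 2020: 14, 2025: 24, 2030: 34}


@dataclass
class ScenarioSpec:
    """Masks, suitability multipliers, and class-area floors encoding one policy."""

    name: str
    immutable_mask: np.ndarray | None = None
    #: (target class code, zone mask or None for everywhere, factor)
    suitability_multipliers: list[tuple[int, np.ndarray | None, float]] = field(
        default_factory=list
    )
    class_area_floors: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, _, factor in self.suitability_multipliers:
            if factor <= 0:
                raise ValueError("suitability multipliers must be positive")
        for code, floor in self.class_area_floors.items():
            if floor < 0:
                raise ValueError(f"negative floor for class {code}")


def build_scenario(
    name: str,
    baseline_areas: dict[int, float] | None = None,
    permanent_farmland_mask: np.ndarray | None = None,
    conservation_grade1_mask: np.ndarray | None = None,
    conservation_grade2_mask: np.ndarray | None = None,
    farmland_code: int = 1,
    forest_code: int = 2,
    built_up_code: int = 3,
    water_code: int = 4,
) -> ScenarioSpec:
    """Construct one of the four policy scenario specs.

    ``baseline_areas`` are the 2013 class areas (ha) used for floors (S2/S3).
    S2 requires the permanent-farmland mask; S3 the conservation-zone masks.
    """
    if name == "S1":
        return ScenarioSpec("S1")
    if name == "S2":
        if permanent_farmland_mask is None:
            raise ValueError("S2 requires the permanent-farmland mask")
        if baseline_areas is None:
            raise ValueError("S2 requires baseline class areas")
        return ScenarioSpec(
            "S2",
            immutable_mask=permanent_farmland_mask.astype(bool),
            class_area_floors={farmland_code: baseline_areas[farmland_code]},
        )
    if name == "S3":
        if conservation_grade1_mask is None or conservation_grade2_mask is None:
            raise ValueError("S3 requires both conservation-zone masks")
        if baseline_areas is None:
            raise ValueError("S3 requires baseline class areas")
        mult = [
            (forest_code, conservation_grade1_mask.astype(bool), 1.2),
            (water_code, conservation_grade1_mask.astype(bool), 1.2),
            (forest_code, conservation_grade2_mask.astype(bool), 1.1),
            (water_code, conservation_grade2_mask.astype(bool), 1.1),
        ]
        return ScenarioSpec(
            "S3",
            suitability_multipliers=mult,
            class_area_floors={
                forest_code: baseline_areas[forest_code],
                water_code: baseline_areas[water_code],
            },
        )
    if name == "S4":
        return ScenarioSpec("S4", suitability_multipliers=[(built_up_code, None, 1.2)])
    raise ValueError(f"unknown scenario {name!r}; expected S1..S4")


def apply_scenario(
    spec: ScenarioSpec,
    suit: SuitabilityStack,
    config: SimulationConfig,
) -> tuple[SuitabilityStack, SimulationConfig]:
    """Adjust suitability surfaces and simulation config for one scenario.

    Multipliers are applied to every transition into their target class over
    their zone mask, then clipped to [0, 1]; the immutable mask and floors
    are merged into the config.  An empty spec returns the inputs unchanged.
    """
    surfaces = {k: v.copy() for k, v in suit.surfaces.items()}
    for target, mask, factor in spec.suitability_multipliers:
        for (i, j), surf in surfaces.items():
            if j != target or i == j:
                continue
            if mask is None:
                surf *= factor
            else:
                surf[mask] *= factor
            np.clip(surf, 0.0, 1.0, out=surf)
    new_config = replace(
        config,
        immutable_mask=(
            spec.immutable_mask
            if config.immutable_mask is None
            else (
                config.immutable_mask
                if spec.immutable_mask is None
                else config.immutable_mask | spec.immutable_mask
            )
        ),
        class_area_floors={**config.class_area_floors, **spec.class_area_floors},
    )
    return SuitabilityStack(surfaces, suit.shape), new_config


def enforce_floors(
    state: LandCoverGrid,
    demands: np.ndarray,
    floors: dict[int, float],
) -> np.ndarray:
    """Cap per-pair out-demands so floored classes never dip below their minimum.

    Pro-rata capping with largest-remainder rounding; the simulator applies
    this every iteration, so floors hold throughout a run, not just at
    snapshots.
    """
    return cap_demands_to_floors(state, demands, floors)


def _extended_schedule(
    tm: TransitionMatrix, cell_area_ha: float, horizon: int, calibration_iterations: int
) -> np.ndarray:
    """Per-iteration demands for a horizon past the calibration window.

    The calibrated matrix fixes demands for one ``calibration_iterations``
    cycle; longer horizons reapply the per-period demands cyclically, which
    keeps each iteration's conversion intensity at the calibrated level
    without assuming the nine-year matrix can be linearly rescaled.
    """
    from .ca import demand_schedule

    base = demand_schedule(tm, calibration_iterations, cell_area_ha)
    idx = np.arange(horizon) % calibration_iterations
    return base[idx]


def run_projection(
    initial: LandCoverGrid,
    tm: TransitionMatrix,
    suit: SuitabilityStack,
    specs: list[ScenarioSpec],
    zones: ZoneGrid | None = None,
    config: SimulationConfig | None = None,
    snapshot_years: tuple[int, ...] = (2015, 2020, 2025, 2030),
    weights: DisturbanceWeights = DisturbanceWeights(),
    calibration_iterations: int = 18,
) -> dict[str, dict]:
    """Project each scenario from 2013 and evaluate zonal risk trajectories.

    Returns, per scenario name: ``snapshots`` ({year: LandCoverGrid}),
    ``risk`` (zonal risk per snapshot year incl. the 2013 baseline, jointly
    normalized), and ``change_ratio`` ((R_t - R_2013) / R_2013 per zone).
    """
    bad = [y for y in snapshot_years if y not in SNAPSHOT_ITERATIONS]
    if bad:
        raise ValueError(f"snapshot years {bad} not on the half-year grid")
    horizon = max(SNAPSHOT_ITERATIONS[y] for y in snapshot_years)
    base_config = config or SimulationConfig()
    schedule = _extended_schedule(
        tm, initial.cell_area_ha, horizon, calibration_iterations
    )
    results: dict[str, dict] = {}
    for spec in specs:
        adj_suit, adj_config = apply_scenario(spec, suit, base_config)
        adj_config = replace(adj_config, iterations=horizon)
        iters = sorted(SNAPSHOT_ITERATIONS[y] for y in snapshot_years)
        states, report = simulate(
            initial, tm, adj_suit, adj_config, snapshots=iters, schedule=schedule
        )
        snapshots = {2013: states[0]}
        for year, st in zip(sorted(snapshot_years), states[1:]):
            snapshots[year] = st
        risk = zonal_risk(
            {str(y): snapshots[y] for y in sorted(snapshots)},
            zones=zones,
            weights=weights,
        )
        base = risk[risk["date"] == "2013"].set_index("unit")["R"]
        risk = risk.assign(
            change_ratio=[
                (row.R - base[row.unit]) / base[row.unit]
                if row.defined and base.get(row.unit)
                else float("nan")
                for row in risk.itertuples()
            ]
        )
        results[spec.name] = {
            "snapshots": snapshots,
            "risk": risk,
            "report": report,
        }
    return results
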