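"""Project the four policy scenarios to 2030 and track zonal risk.

From the synthetic later-date landscape (the 2013 analog), runs the four
scenarios - S1 status quo, S2 permanent-farmland protection, S3 ecological
conservation, S4 urban development - on half-year steps to 2030 with
snapshots at 2015/2020/2025/2030, and writes per-zone risk trajectories,
change ratios vs the start year, and class-area trajectories.
"""

import warnings
from pathlib import Path

import pandas as pd

from landrisk import ca, change, lssvm, scenarios
from landrisk.grid import EZHOU_SCHEME
from landrisk.synthetic import SyntheticSpec, make_world

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    world = make_world(SyntheticSpec(seed=seed))
    t1, t2, zones, masks = world["t1"], world["t2"], world["zones"], world["masks"]
    tm = change.cross_tabulate(t1, t2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack, _ = lssvm.build_suitability_stack(
            t1, t2, world["drivers"], n_per_type=500, seed=seed
        )

    baseline = t2.class_areas_ha()
    specs = [
        scenarios.build_scenario("S1"),
        scenarios.build_scenario(
            "S2", baseline_areas=baseline,
            permanent_farmland_mask=masks["permanent_farmland"],
        ),
        scenarios.build_scenario(
            "S3", baseline_areas=baseline,
            conservation_grade1_mask=masks["conservation_grade1"],
            conservation_grade2_mask=masks["conservation_grade2"],
        ),
        scenarios.build_scenario("S4"),
    ]
    results = scenarios.run_projection(
        t2, tm, stack, specs, zones=zones, config=ca.SimulationConfig(seed=seed)
    )

    risk_frames, area_rows = [], []
    for name, res in results.items():
        risk_frames.append(res["risk"].assign(scenario=name))
        for year, grid in sorted(res["snapshots"].items()):
            areas = grid.class_areas_ha()
            for code, area in areas.items():
                area_rows.append((name, year, EZHOU_SCHEME.name_of(code), area))
    risk_df = pd.concat(risk_frames, ignore_index=True)
    area_df = pd.DataFrame(area_rows, columns=["scenario", "year", "class", "area_ha"])

    OUT.mkdir(exist_ok=True)
    risk_df.to_csv(OUT / "scenario_zonal_risk.csv", index=False)
    area_df.to_csv(OUT / "scenario_class_areas.csv", index=False)

    pivot = area_df.pivot_table(
        index=["scenario", "year"], columns="class", values="area_ha"
    )[list(EZHOU_SCHEME.names)]
    print(pivot.to_string(float_format=lambda v: f"{v:,.0f}"))
    mean_risk = risk_df[risk_df.defined].groupby(["scenario", "date"])["R"].mean()
    print("\nmean zonal risk:\n" + mean_risk.to_string(float_format=lambda v: f"{v:.3f}"))
    print(
        "\nS2 pins farmland at its start-year floor; S3 slows forest/water "
        "loss inside conservation zones; S4 steers development toward "
        "road-accessible cells without changing demanded quantities."
    )


if __name__ == "__main__":
    main()
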