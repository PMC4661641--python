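"""Landscape ecological risk: disturbance x vulnerability, evaluated per zone.

The risk index for an analysis unit is

    R = sum_i alpha_i * sqrt(D_i * V_i)

where alpha_i is the class area share within the unit, D_i the landscape
disturbance index (a weighted sum of min-max normalized class-level SPLIT
and PD plus the unit-level SHDI; default weights 0.3 / 0.5 / 0.2), and V_i
the normalized ordinal vulnerability grade of the class.  Since D, V and
alpha all live in [0, 1] and the alphas sum to one, R lies in [0, 1] and is
classified in five 0.2-wide bands from low to high.

Normalization cohort: by default metrics are min-max normalized jointly
across every (zone, class, date) observation of one analysis call, which
keeps risk values comparable across dates; a per-date mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ClassScheme, LandCoverGrid, ZoneGrid, align_check
from .metrics import label_patches, patch_density, shdi, splitting_index

__all__ = [
    "DisturbanceWeights",
    "normalize_metrics",
    "disturbance_index",
    "vulnerability_index",
    "landscape_risk",
    "categorize_risk",
    "RISK_CATEGORIES",
    "zonal_risk",
]

RISK_CATEGORIES = ("low", "relatively_low", "medium", "relatively_high", "high")


@dataclass(frozen=True)
class DisturbanceWeights:
    """Weights on normalized SPLIT, PD, and SHDI in the disturbance index."""

    w_split: float = 0.3
    w_pd: float = 0.5
    w_shdi: float = 0.2

    def __post_init__(self) -> None:
        if min(self.w_split, self.w_pd, self.w_shdi) < 0:
            raise ValueError("disturbance weights must be non-negative")
        if self.w_split + self.w_pd + self.w_shdi == 0:
            raise ValueError("disturbance weights must not all be zero")


def normalize_metrics(values) -> np.ndarray:
    """Min-max normalize a collection of raw metric values to [0, 1].

    A constant collection carries no relative disturbance signal and maps to
    all zeros (with a warning).  NaNs pass through.
    """
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("cannot normalize an empty collection")
    finite = a[np.isfinite(a)]
    if finite.size == 0:
        return a
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        warnings.warn("constant metric collection normalized to 0", stacklevel=2)
        out = np.where(np.isfinite(a), 0.0, a)
        return out
    return (a - lo) / (hi - lo)


def disturbance_index(
    split_n: float, pd_n: float, shdi_n: float, w: DisturbanceWeights = DisturbanceWeights()
) -> float:
    """D_i = w1*SPLIT'_i + w2*PD'_i + w3*SHDI' (all inputs already in [0, 1]).

    SHDI carries no class subscript: the unit-level value is shared by every
    class of the unit.
    """
    return w.w_split * split_n + w.w_pd * pd_n + w.w_shdi * shdi_n


def vulnerability_index(scheme: ClassScheme, method: str = "sum") -> dict[int, float]:
    """Normalized vulnerability per class code.

    ``sum``  (default): grade / sum(grades) — keeps every V_i > 0 so the
    lowest-grade class still contributes to risk.
    ``minmax``: (grade - min) / (max - min) — zeroes the lowest grade.
    """
    grades = np.asarray(scheme.vulnerability_grades, dtype=float)
    if method == "sum":
        v = grades / grades.sum()
    elif method == "minmax":
        v = (grades - grades.min()) / (grades.max() - grades.min())
    else:
        raise ValueError(f"unknown vulnerability normalization {method!r}")
    return {code: float(v[k]) for k, code in enumerate(scheme.codes)}


def landscape_risk(alpha, D, V) -> float:
    """R = sum_i alpha_i * sqrt(D_i * V_i); all inputs in [0, 1], alphas sum to 1."""
    alpha = np.asarray(alpha, dtype=float)
    D = np.asarray(D, dtype=float)
    V = np.asarray(V, dtype=float)
    if (alpha < 0).any() or (D < 0).any() or (V < 0).any():
        raise ValueError("risk inputs must be non-negative")
    if not np.isclose(alpha.sum(), 1.0, atol=1e-6):
        raise ValueError(f"area shares must sum to 1, got {alpha.sum()}")
    return float((alpha * np.sqrt(D * V)).sum())


def categorize_risk(r: float) -> str:
    """Five categories on 0.2-wide bands; bins right-closed, first includes 0."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"risk value {r} outside [0, 1]")
    if r <= 0.2:
        return "low"
    if r <= 0.4:
        return "relatively_low"
    if r <= 0.6:
        return "medium"
    if r <= 0.8:
        return "relatively_high"
    return "high"


def _zone_observations(
    grid: LandCoverGrid,
    zones: ZoneGrid | None,
    date: str,
    connectivity: int,
) -> list[dict]:
    """Raw per-(zone, class) SPLIT/PD and per-zone SHDI observations."""
    obs: list[dict] = []
    if zones is None:
        zone_iter = [("landscape", grid.valid_mask)]
    else:
        align_check([grid, zones]).raise_if_failed()
        zone_iter = [
            (str(z), (zones.values == z) & grid.valid_mask) for z in zones.zone_ids()
        ]
    for unit, mask in zone_iter:
        if not mask.any():
            obs.append({"date": date, "unit": unit, "empty": True})
            continue
        sub_values = np.where(mask, grid.values, grid.nodata)
        sub = LandCoverGrid(sub_values, grid.cell_size, grid.origin, grid.nodata, grid.scheme)
        ps = label_patches(sub, connectivity)
        total = ps.total_area_ha
        areas = sub.class_areas_ha()
        unit_shdi = shdi(areas)
        for code in grid.scheme.codes:
            if areas[code] == 0:
                continue
            obs.append(
                {
                    "date": date,
                    "unit": unit,
                    "empty": False,
                    "class_code": code,
                    "alpha": areas[code] / total,
                    "split": splitting_index(ps, class_code=code),
                    "pd": patch_density(ps, class_code=code),
                    "shdi": unit_shdi,
                }
            )
    return obs


def zonal_risk(
    grids: dict[str, LandCoverGrid] | LandCoverGrid,
    zones: ZoneGrid | None = None,
    weights: DisturbanceWeights = DisturbanceWeights(),
    vulnerability: str = "sum",
    normalization: str = "joint",
    connectivity: int = 8,
    detail: bool = False,
) -> pd.DataFrame:
    """Ecological risk per zone and date.

    Parameters
    ----------
    grids : one grid or a {date: grid} mapping; multiple dates are
        normalized together when ``normalization='joint'`` (default) or
        within each date when ``'per_date'``.
    detail : also return the per-class alpha / D / V breakdown.

    Returns a frame with date, unit, R, category (and the breakdown when
    ``detail``); empty zones get NaN risk flagged ``defined=False``.
    """
    if isinstance(grids, LandCoverGrid):
        grids = {"": grids}
    if normalization not in ("joint", "per_date"):
        raise ValueError(f"unknown normalization {normalization!r}")
    all_obs: list[dict] = []
    for date, grid in grids.items():
        all_obs.extend(_zone_observations(grid, zones, date, connectivity))
    obs = pd.DataFrame([o for o in all_obs if not o.get("empty")])
    empties = [(o["date"], o["unit"]) for o in all_obs if o.get("empty")]
    if not obs.empty:
        groups = [obs] if normalization == "joint" else [g for _, g in obs.groupby("date")]
        for g in groups:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                obs.loc[g.index, "split_n"] = normalize_metrics(g["split"].to_numpy())
                obs.loc[g.index, "pd_n"] = normalize_metrics(g["pd"].to_numpy())
                obs.loc[g.index, "shdi_n"] = normalize_metrics(g["shdi"].to_numpy())
        scheme = next(iter(grids.values())).scheme
        V = vulnerability_index(scheme, vulnerability)
        obs["D"] = [
            disturbance_index(s, p, h, weights)
            for s, p, h in zip(obs["split_n"], obs["pd_n"], obs["shdi_n"])
        ]
        obs["V"] = [V[c] for c in obs["class_code"]]
    rows = []
    if not obs.empty:
        for (date, unit), g in obs.groupby(["date", "unit"], sort=False):
            r = landscape_risk(g["alpha"].to_numpy(), g["D"].to_numpy(), g["V"].to_numpy())
            rows.append(
                {"date": date, "unit": unit, "R": r, "category": categorize_risk(r), "defined": True}
            )
    for date, unit in empties:
        rows.append({"date": date, "unit": unit, "R": float("nan"), "category": None, "defined": False})
    result = pd.DataFrame(rows, columns=["date", "unit", "R", "category", "defined"])
    if detail:
        return result, obs
    return result
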