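"""FRAGSTATS-style landscape metrics from categorical rasters.

Five metrics at class and landscape level: splitting index (SPLIT), patch
density (PD), contagion (CONTAG), perimeter-area fractal dimension (PAFRAC),
and Shannon's diversity index (SHDI).  Conventions (stated here because the
published definitions leave them open and results depend on them):

* patches are 8-connected components of same-class cells (configurable to 4);
* patch perimeter counts cell edges adjoining a different class, nodata, or
  the grid boundary;
* CONTAG adjacencies are 4-neighbor, double-counted (each internal edge seen
  from both sides), like-adjacencies included, nodata edges excluded;
* PAFRAC = 2 / b with b the OLS slope of ln(area) on ln(perimeter) over
  patches, flagged (not clipped) when outside [1, 2];
* zonal metrics delineate patches inside the zone mask only, with the zone's
  valid extent as the landscape area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import LandCoverGrid, ZoneGrid, align_check

__all__ = [
    "PatchSet",
    "label_patches",
    "shdi",
    "patch_density",
    "splitting_index",
    "contagion",
    "adjacency_matrix",
    "pafrac",
    "metric_table",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class PatchSet:
    """Patches of a categorical raster: class code, area (ha), perimeter (m), cells."""

    class_codes: np.ndarray  # (n_patches,)
    areas_ha: np.ndarray
    perimeters_m: np.ndarray
    cell_counts: np.ndarray
    total_area_ha: float  # non-nodata landscape area
    connectivity: int

    @property
    def n_patches(self) -> int:
        return len(self.class_codes)

    def of_class(self, code: int) -> "PatchSet":
        sel = self.class_codes == code
        return PatchSet(
            self.class_codes[sel],
            self.areas_ha[sel],
            self.perimeters_m[sel],
            self.cell_counts[sel],
            self.total_area_ha,
            self.connectivity,
        )


def _edge_count(member: np.ndarray) -> np.ndarray:
    """Per-cell count of edges adjoining a different class, nodata, or the boundary."""
    # Pad with non-members so boundary edges count.
    pm = np.pad(member, 1, constant_values=False)
    edges = np.zeros(member.shape, dtype=np.int64)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = pm[1 + dr : pm.shape[0] - 1 + dr, 1 + dc : pm.shape[1] - 1 + dc]
        edges += member & ~nb
    return edges


def label_patches(grid: LandCoverGrid, connectivity: int = 8) -> PatchSet:
    """Delineate same-class connected components and measure area and perimeter."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    valid = grid.valid_mask
    codes_out: list[np.ndarray] = []
    areas: list[np.ndarray] = []
    perims: list[np.ndarray] = []
    counts: list[np.ndarray] = []
    for code in grid.scheme.codes:
        member = grid.values == code
        if not member.any():
            continue
        labels, n = ndimage.label(member, structure=struct)
        cells = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        edge = _edge_count(member)
        perim = np.bincount(labels.ravel(), weights=edge.ravel(), minlength=n + 1)[1:]
        codes_out.append(np.full(n, code))
        counts.append(cells)
        areas.append(cells * grid.cell_area_ha)
        perims.append(perim * grid.cell_size)
    if codes_out:
        class_codes = np.concatenate(codes_out)
        areas_ha = np.concatenate(areas)
        perimeters = np.concatenate(perims)
        cell_counts = np.concatenate(counts)
    else:
        class_codes = np.empty(0, dtype=int)
        areas_ha = perimeters = np.empty(0)
        cell_counts = np.empty(0, dtype=int)
    total = float(valid.sum() * grid.cell_area_ha)
    return PatchSet(class_codes, areas_ha, perimeters, cell_counts, total, connectivity)


def shdi(class_areas) -> float:
    """Shannon's diversity index over class area shares: -sum p ln p."""
    a = np.asarray(
        list(class_areas.values()) if isinstance(class_areas, dict) else class_areas,
        dtype=float,
    )
    total = a.sum()
    if total <= 0:
        raise ValueError("shdi undefined for zero total area")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def patch_density(ps: PatchSet, total_area_ha: float | None = None, class_code: int | None = None) -> float:
    """Patches per 100 ha, for one class or the whole landscape."""
    area = ps.total_area_ha if total_area_ha is None else total_area_ha
    if area <= 0:
        raise ValueError("patch_density undefined for zero area")
    n = ps.n_patches if class_code is None else ps.of_class(class_code).n_patches
    return n / area * 100.0


def splitting_index(ps: PatchSet, total_area_ha: float | None = None, class_code: int | None = None) -> float:
    """SPLIT = A^2 / sum(a_j^2): effective number of equal patches; 1 = one solid patch.

    A is always the total landscape area, including for class-level values.
    """
    area = ps.total_area_ha if total_area_ha is None else total_area_ha
    sub = ps if class_code is None else ps.of_class(class_code)
    if sub.n_patches == 0:
        return float("nan")
    return float(area**2 / (sub.areas_ha**2).sum())


def adjacency_matrix(grid: LandCoverGrid) -> np.ndarray:
    """4-neighbor cell adjacency counts g_ik, double-counted, nodata excluded."""
    n = grid.scheme.n_classes
    lut = np.full(max(grid.scheme.codes) + 1, -1, dtype=np.int64)
    for k, c in enumerate(grid.scheme.codes):
        lut[c] = k
    v = grid.values
    valid = grid.valid_mask
    g = np.zeros((n, n), dtype=np.int64)
    # Horizontal and vertical neighbor pairs, then mirror for double-counting.
    for (a, b), (va, vb) in (
        ((v[:, :-1], v[:, 1:]), (valid[:, :-1], valid[:, 1:])),
        ((v[:-1, :], v[1:, :]), (valid[:-1, :], valid[1:, :])),
    ):
        ok = va & vb
        i = lut[a[ok]]
        j = lut[b[ok]]
        np.add.at(g, (i, j), 1)
        np.add.at(g, (j, i), 1)
    return g


def contagion(grid: LandCoverGrid) -> float:
    """CONTAG (percent): adjacency-entropy measure of aggregation in (0, 100].

    CONTAG = [1 + sum_{i,k} q_ik ln q_ik / (2 ln m)] x 100 with
    q_ik = P_i * g_ik / sum_k g_ik; m counts classes present.
    """
    areas = np.array([v for v in grid.class_areas_ha().values()])
    present = areas > 0
    m = int(present.sum())
    if m < 2:
        raise ValueError("contagion undefined for a single-class landscape")
    P = areas / areas.sum()
    g = adjacency_matrix(grid).astype(float)
    row = g.sum(axis=1)
    ent = 0.0
    for i in np.flatnonzero(present):
        if row[i] == 0:
            continue
        q = P[i] * g[i] / row[i]
        q = q[q > 0]
        ent += float((q * np.log(q)).sum())
    return (1.0 + ent / (2.0 * math.log(m))) * 100.0


def pafrac(ps: PatchSet, class_code: int | None = None) -> tuple[float, bool]:
    """Perimeter-area fractal dimension: 2 / OLS-slope of ln(area) on ln(perimeter).

    Returns (value, defined).  Undefined (nan, False) with fewer than two
    patches or zero variance in ln(perimeter); values outside [1, 2] are
    returned as computed — the defined flag stays True and callers may warn.
    """
    sub = ps if class_code is None else ps.of_class(class_code)
    if sub.n_patches < 2:
        return float("nan"), False
    x = np.log(sub.perimeters_m)
    y = np.log(sub.areas_ha)
    if np.allclose(x, x[0]):
        return float("nan"), False
    slope = float(np.polyfit(x, y, 1)[0])
    if slope == 0:
        return float("nan"), False
    return 2.0 / slope, True


def _crop_to_zone(grid: LandCoverGrid, zone_mask: np.ndarray) -> LandCoverGrid:
    values = np.where(zone_mask, grid.values, grid.nodata)
    return LandCoverGrid(values, grid.cell_size, grid.origin, grid.nodata, grid.scheme)


def _unit_rows(grid: LandCoverGrid, unit: str, connectivity: int) -> list[dict]:
    """All metric rows for one analysis unit (whole landscape or one zone)."""
    rows: list[dict] = []
    ps = label_patches(grid, connectivity)
    total = ps.total_area_ha
    if total == 0:
        return [{"unit": unit, "class": "LAND", "metric": m, "value": float("nan"), "defined": False}
                for m in ("SPLIT", "PD", "CONTAG", "SHDI", "PAFRAC")]
    areas = grid.class_areas_ha()

    def add(cls: str, metric: str, value: float, defined: bool = True) -> None:
        rows.append({"unit": unit, "class": cls, "metric": metric,
                     "value": value, "defined": defined and np.isfinite(value)})

    add("LAND", "SPLIT", splitting_index(ps))
    add("LAND", "PD", patch_density(ps))
    try:
        add("LAND", "CONTAG", contagion(grid))
    except ValueError:
        add("LAND", "CONTAG", float("nan"), False)
    add("LAND", "SHDI", shdi(areas))
    v, ok = pafrac(ps)
    add("LAND", "PAFRAC", v, ok)
    for code in grid.scheme.codes:
        name = grid.scheme.name_of(code)
        if areas[code] == 0:
            for metric in ("SPLIT", "PD", "PAFRAC"):
                add(name, metric, float("nan"), False)
            continue
        add(name, "SPLIT", splitting_index(ps, class_code=code))
        add(name, "PD", patch_density(ps, class_code=code))
        v, ok = pafrac(ps, class_code=code)
        add(name, "PAFRAC", v, ok)
    return rows


def metric_table(
    grid: LandCoverGrid,
    zones: ZoneGrid | None = None,
    connectivity: int = 8,
) -> pd.DataFrame:
    """Class- and landscape-level metrics for the landscape and optionally per zone.

    Zonal rows treat each zone's valid extent as its own landscape: patches
    truncate at zone borders, and SPLIT/PD use the zone area as A.
    Columns: unit, class ('LAND' for landscape level), metric, value, defined.
    """
    rows = _unit_rows(grid, "landscape", connectivity)
    if zones is not None:
        align_check([grid, zones]).raise_if_failed()
        for z in zones.zone_ids():
            sub = _crop_to_zone(grid, zones.values == z)
            rows.extend(_unit_rows(sub, str(z), connectivity))
    return pd.DataFrame(rows, columns=["unit", "class", "metric", "value", "defined"])
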