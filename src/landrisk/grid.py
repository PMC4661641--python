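"""Raster data model and georeferenced I/O shared by every analysis stage.

Rasters are plain 2-D numpy arrays with a minimal georeference: square cells,
north-up, row-major, cell (0, 0) in the upper-left corner.  Categorical land
cover travels as :class:`LandCoverGrid` (integer codes validated against a
:class:`ClassScheme`), continuous driver surfaces as a :class:`DriverStack`.
Two on-disk formats are supported: ESRI ASCII grid (the canonical,
human-readable fixture format) and single-band GeoTIFF (ModelPixelScale /
ModelTiepoint tags via tifffile).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ClassScheme",
    "EZHOU_SCHEME",
    "LandCoverGrid",
    "ZoneGrid",
    "DriverStack",
    "DRIVER_NAMES",
    "AlignmentReport",
    "read_grid",
    "write_grid",
    "align_check",
    "distance_surface",
    "slope_surface",
]

#: Driver surfaces used to learn transition suitability, in canonical order.
DRIVER_NAMES = (
    "distance_highway",
    "distance_railway",
    "distance_roads",
    "distance_town_centers",
    "distance_urban_centers",
    "distance_water",
    "elevation",
    "slope",
)


class GridValidationError(ValueError):
    """Raised when raster values or headers violate the data model."""


@dataclass(frozen=True)
class ClassScheme:
    """Land-cover class codes, labels, and ordinal vulnerability grades.

    The vulnerability grade ranks how sensitive each cover type is to
    external disturbance (1 = most stable, 6 = most fragile).  Managed
    covers (built-up, plantation forest, farmland) rank low; unmanaged
    covers (water, open/other land) rank high.
    """

    codes: tuple[int, ...]
    names: tuple[str, ...]
    vulnerability_grades: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise GridValidationError("class codes must be unique")
        if not (len(self.codes) == len(self.names) == len(self.vulnerability_grades)):
            raise GridValidationError("codes, names and grades must have equal length")
        for g in self.vulnerability_grades:
            if not 1 <= g <= 6:
                raise GridValidationError(f"vulnerability grade {g} outside 1..6")

    @property
    def n_classes(self) -> int:
        return len(self.codes)

    def index_of(self, code: int) -> int:
        return self.codes.index(code)

    def name_of(self, code: int) -> str:
        return self.names[self.index_of(code)]

    def grade_of(self, code: int) -> int:
        return self.vulnerability_grades[self.index_of(code)]

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, tuple[str, int]]) -> "ClassScheme":
        codes = tuple(mapping)
        names = tuple(mapping[c][0] for c in codes)
        grades = tuple(mapping[c][1] for c in codes)
        return cls(codes, names, grades)


#: The six-class scheme used throughout: farmland, forest, built-up, water,
#: aquaculture, other open land.  Grades: built-up 1 (lowest vulnerability),
#: forest 2, farmland 3, aquaculture 4, water 5, other 6 (highest).
EZHOU_SCHEME = ClassScheme(
    codes=(1, 2, 3, 4, 5, 6),
    names=("farmland", "forest", "built_up", "water", "aquaculture", "other"),
    vulnerability_grades=(3, 2, 1, 5, 4, 6),
)


def _validate_values(values: np.ndarray, scheme: ClassScheme, nodata: int) -> None:
    present = np.unique(values)
    bad = [int(v) for v in present if v != nodata and v not in scheme.codes]
    if bad:
        raise GridValidationError(
            f"grid contains codes {bad} not in scheme codes {list(scheme.codes)}"
        )


@dataclass
class LandCoverGrid:
    """Categorical raster: integer class codes on a square-cell lattice."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of the upper-left corner
    nodata: int = -9999
    scheme: ClassScheme = EZHOU_SCHEME

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GridValidationError("grid values must be 2-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise GridValidationError("land-cover values must be integers")
        if self.cell_size <= 0:
            raise GridValidationError("cell_size must be positive")
        _validate_values(self.values, self.scheme, self.nodata)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def class_areas_ha(self) -> dict[int, float]:
        """Hectares per class code (nodata excluded)."""
        return {
            int(c): float(np.count_nonzero(self.values == c) * self.cell_area_ha)
            for c in self.scheme.codes
        }

    def copy(self) -> "LandCoverGrid":
        return replace(self, values=self.values.copy())


@dataclass
class ZoneGrid:
    """Integer zone labels (towns / analysis regions) aligned to a land-cover grid."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GridValidationError("zone values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def zone_ids(self) -> list[int]:
        ids = np.unique(self.values)
        return [int(z) for z in ids if z != self.nodata]


@dataclass
class DriverStack:
    """Aligned continuous surfaces (distances, elevation, slope) for suitability models."""

    surfaces: dict[str, np.ndarray]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.surfaces.values()}
        if len(shapes) > 1:
            raise GridValidationError(f"driver surfaces disagree in shape: {shapes}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.surfaces)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.surfaces.values())).shape

    def feature_matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Stack driver values at (rows, cols) into an (n, n_drivers) matrix."""
        return np.column_stack([self.surfaces[n][rows, cols] for n in self.names])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_ascii(path: Path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    header: dict[str, float] = {}
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    required = {"ncols", "nrows", "cellsize"}
    missing = required - set(header)
    if missing:
        raise GridValidationError(f"ASCII grid header missing {sorted(missing)}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    body = " ".join(lines[i:])
    data = np.array(body.split(), dtype=float)
    if data.size != nrows * ncols:
        raise GridValidationError(
            f"ASCII grid body has {data.size} values, expected {nrows * ncols}"
        )
    values = data.reshape(nrows, ncols)
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    origin = (xll, yll + nrows * header["cellsize"])  # upper-left corner
    return values, header["cellsize"], origin, nodata


def read_grid(
    path: str | Path,
    format: str | None = None,
    scheme: ClassScheme | None = None,
    categorical: bool = True,
):
    """Read a raster as a :class:`LandCoverGrid` (categorical) or bare surface.

    Parameters
    ----------
    path : file path; format inferred from suffix if ``format`` is None
        (``.asc`` → ascii_grid, ``.tif``/``.tiff`` → geotiff).
    categorical : if True, values are validated against ``scheme`` (default
        the six-class scheme) and returned as a LandCoverGrid; otherwise a
        ``(values, cell_size, origin, nodata)`` tuple of floats is returned.
    """
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "ascii_grid"
    if format == "ascii_grid":
        values, cell_size, origin, nodata = _parse_ascii(path)
    elif format == "geotiff":
        values, cell_size, origin, nodata = _read_geotiff(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not categorical:
        return values, cell_size, origin, nodata
    ivalues = values.astype(np.int64)
    if not np.allclose(values, ivalues):
        raise GridValidationError("categorical grid contains non-integer values")
    return LandCoverGrid(
        values=ivalues,
        cell_size=cell_size,
        origin=origin,
        nodata=int(nodata),
        scheme=scheme or EZHOU_SCHEME,
    )


def write_grid(
    grid,
    path: str | Path,
    format: str | None = None,
    values: np.ndarray | None = None,
) -> None:
    """Write a LandCoverGrid / ZoneGrid (or ``values`` with grid georeference)."""
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "ascii_grid"
    data = grid.values if values is None else values
    nrows, ncols = data.shape
    nodata = grid.nodata
    if format == "ascii_grid":
        xll = grid.origin[0]
        yll = grid.origin[1] - nrows * grid.cell_size
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {xll:.6f}\n"
            f"yllcorner {yll:.6f}\n"
            f"cellsize {grid.cell_size:.6f}\n"
            f"NODATA_value {nodata}\n"
        )
        if np.issubdtype(np.asarray(data).dtype, np.integer):
            body = "\n".join(" ".join(str(int(v)) for v in row) for row in data)
        else:
            body = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in data)
        path.write_text(header + body + "\n")
    elif format == "geotiff":
        _write_geotiff(path, np.asarray(data), grid.cell_size, grid.origin, nodata)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_geotiff(path, values, cell_size, origin, nodata) -> None:
    import tifffile

    # Minimal GeoTIFF georeference: pixel scale + upper-left tiepoint + nodata.
    scale = (float(cell_size), float(cell_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)
    extratags = [
        (33550, "d", 3, scale, True),
        (33922, "d", 6, tiepoint, True),
        (42113, "s", 0, str(nodata), True),
    ]
    tifffile.imwrite(path, values, extratags=extratags)


def _read_geotiff(path):
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        scale = tags.get(33550)
        tie = tags.get(33922)
        nod = tags.get(42113)
        if scale is None or tie is None:
            raise GridValidationError("GeoTIFF lacks ModelPixelScale/ModelTiepoint tags")
        cell_size = float(scale.value[0])
        origin = (float(tie.value[3]), float(tie.value[4]))
        nodata = float(nod.value) if nod is not None else -9999.0
    return values, cell_size, origin, nodata


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentReport:
    ok: bool
    mismatches: list[str] = field(default_factory=list)

    def raise_if_failed(self) -> None:
        if not self.ok:
            raise GridValidationError("grids are misaligned: " + "; ".join(self.mismatches))


def align_check(grids: Sequence) -> AlignmentReport:
    """Check that all inputs share shape, cell size, and origin.

    Origins must agree within 1e-6 of a cell.  Report-only: callers decide
    whether a failed report is fatal (pipeline stages treat it as such).
    """
    if len(grids) < 2:
        raise ValueError("align_check needs at least two grids")
    ref = grids[0]
    mismatches: list[str] = []
    for k, g in enumerate(grids[1:], start=1):
        if g.shape != ref.shape:
            mismatches.append(f"input {k}: shape {g.shape} != {ref.shape}")
        if not math.isclose(g.cell_size, ref.cell_size, rel_tol=0, abs_tol=1e-9):
            mismatches.append(f"input {k}: cellsize {g.cell_size} != {ref.cell_size}")
        tol = 1e-6 * ref.cell_size
        if (
            abs(g.origin[0] - ref.origin[0]) > tol
            or abs(g.origin[1] - ref.origin[1]) > tol
        ):
            mismatches.append(f"input {k}: origin {g.origin} != {ref.origin}")
    return AlignmentReport(ok=not mismatches, mismatches=mismatches)


# ---------------------------------------------------------------------------
# Driver-surface derivation
# ---------------------------------------------------------------------------

def distance_surface(targets: np.ndarray, cell_size: float) -> np.ndarray:
    """Euclidean distance (meters, between cell centers) to the nearest target cell.

    Exact distance transform; zero on target cells.
    """
    targets = np.asarray(targets, dtype=bool)
    if not targets.any():
        raise ValueError("distance_surface: target set is empty")
    return ndimage.distance_transform_edt(~targets, sampling=cell_size)


def slope_surface(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    """Slope in degrees from a DEM using Horn's 3x3 finite differences.

    Border cells use edge replication so the kernel is defined everywhere.
    """
    z = np.asarray(elevation, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("slope_surface needs at least a 3x3 grid")
    if not np.all(np.isfinite(z)):
        raise ValueError("elevation must be finite")
    p = np.pad(z, 1, mode="edge")
    # Horn weights: corners 1, edge-neighbors 2, normalized by 8*cell.
    dzdx = (
        (p[:-2, 2:] + 2 * p[1:-1, 2:] + p[2:, 2:])
        - (p[:-2, :-2] + 2 * p[1:-1, :-2] + p[2:, :-2])
    ) / (8 * cell_size)
    dzdy = (
        (p[2:, :-2] + 2 * p[2:, 1:-1] + p[2:, 2:])
        - (p[:-2, :-2] + 2 * p[:-2, 1:-1] + p[:-2, 2:])
    ) / (8 * cell_size)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
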