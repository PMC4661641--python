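"""Seeded synthetic landscapes, drivers, and ground-truth transition processes.

Every stage of the pipeline is testable without the (undeposited) source
rasters: this module generates spatially autocorrelated categorical
landscapes with controlled class proportions, driver surfaces built from
random line/point features and a fractal DEM, Voronoi analysis zones, and a
later-date landscape evolved under a known multinomial-logit transition
model whose exact per-cell probabilities are returned alongside the
realization.  All generators are fully deterministic under their seed.

The default world mirrors the study conditions at desk scale: 150 x 150
cells of 100 m (22,500 cells = 2250 ha), six classes at the region's 2004
area proportions, nine zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import (
    DRIVER_NAMES,
    DriverStack,
    EZHOU_SCHEME,
    LandCoverGrid,
    ZoneGrid,
    distance_surface,
    slope_surface,
)
from .tables import fixtures  # noqa: F401  (re-exported: printed-table fixtures)

__all__ = [
    "SyntheticSpec",
    "generate_landscape",
    "generate_zones",
    "generate_drivers",
    "generate_masks",
    "evolve_landscape",
    "make_world",
    "fixtures",
]

#: 2004 class proportions of the study region (farmland, forest, built-up,
#: water, aquaculture, other), renormalized to sum to 1.
_DEFAULT_PROPORTIONS = (0.4436, 0.0570, 0.1169, 0.2044, 0.1231, 0.0551)


def _default_coeffs() -> dict[int, dict[str, float]]:
    # Monotone driver dependences for conversion targets: development pulls
    # toward roads and urban centers, aquaculture toward water, forest uphill.
    return {
        3: {"distance_roads": -2.0, "distance_urban_centers": -1.5},
        5: {"distance_water": -2.0},
        2: {"slope": 1.5},
        1: {"slope": -0.8},
    }


def _default_base() -> np.ndarray:
    # Base log-odds = log of the observed 2004-2013 transition frequencies of
    # the study region, so one synthetic step carries the same change
    # intensity as the region's nine-year interval before driver and
    # neighborhood effects modulate it.
    from .tables import transition_2004_2013

    tm = transition_2004_2013()
    p = tm.area / tm.area.sum(axis=1, keepdims=True)
    return np.log(p)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic world."""

    shape: tuple[int, int] = (150, 150)
    cell_size: float = 100.0
    proportions: tuple[float, ...] = _DEFAULT_PROPORTIONS
    autocorr_length: float = 6.0  # cells; 0 = iid noise
    n_zones: int = 9
    dem_relief: float = 80.0  # meters of elevation range
    dem_roughness: float = 1.0  # 0 = flat DEM
    base_logodds: np.ndarray = field(default_factory=_default_base)
    driver_coeffs: dict[int, dict[str, float]] = field(default_factory=_default_coeffs)
    neighborhood_coeff: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any():
            raise ValueError("proportions must be non-negative")
        self.proportions = tuple(p / p.sum())
        if self.autocorr_length < 0:
            raise ValueError("autocorrelation length must be >= 0")


def _smooth_noise(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    if length > 0:
        z = ndimage.gaussian_filter(z, sigma=length, mode="reflect")
        z /= z.std() or 1.0
    return z


def generate_landscape(spec: SyntheticSpec, seed: int | None = None) -> LandCoverGrid:
    """Autocorrelated categorical landscape with calibrated class shares.

    One smooth latent Gaussian field per class plus a class offset; each cell
    takes the argmax class.  Offsets are calibrated iteratively so empirical
    shares track the requested proportions (within ~3 percentage points on
    grids of 100 x 100 and larger).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = len(spec.proportions)
    fields = np.stack(
        [_smooth_noise(rng, spec.shape, spec.autocorr_length) for _ in range(n)]
    )
    target = np.asarray(spec.proportions)
    offsets = np.log(np.maximum(target, 1e-9))
    ncells = spec.shape[0] * spec.shape[1]
    for _ in range(60):
        cls = np.argmax(fields + offsets[:, None, None], axis=0)
        share = np.bincount(cls.ravel(), minlength=n) / ncells
        err = target - share
        if np.abs(err).max() < 0.002:
            break
        offsets += 0.5 * np.log((target + 1e-4) / (share + 1e-4))
    values = np.asarray(EZHOU_SCHEME.codes)[cls]
    return LandCoverGrid(values.astype(np.int64), spec.cell_size, scheme=EZHOU_SCHEME)


def generate_zones(spec: SyntheticSpec, seed: int | None = None) -> ZoneGrid:
    """Voronoi partition of the grid into ``n_zones`` labeled regions (1-based)."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 101)
    H, W = spec.shape
    pts = np.column_stack([rng.uniform(0, H, spec.n_zones), rng.uniform(0, W, spec.n_zones)])
    rr, cc = np.mgrid[0:H, 0:W]
    d2 = (rr[None] - pts[:, 0, None, None]) ** 2 + (cc[None] - pts[:, 1, None, None]) ** 2
    zones = np.argmin(d2, axis=0) + 1
    return ZoneGrid(zones.astype(np.int64), spec.cell_size)


def _polyline_mask(rng: np.random.Generator, shape, n_lines: int) -> np.ndarray:
    """Rasterize random straight polylines (e.g., a highway) onto the grid."""
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_lines):
        r0, c0 = rng.uniform(0, H), rng.uniform(0, W)
        angle = rng.uniform(0, np.pi)
        length = float(np.hypot(H, W))
        t = np.linspace(-length, length, int(4 * length))
        rr = np.clip((r0 + t * np.sin(angle)).astype(int), 0, H - 1)
        cc = np.clip((c0 + t * np.cos(angle)).astype(int), 0, W - 1)
        inside = (r0 + t * np.sin(angle) >= 0) & (r0 + t * np.sin(angle) < H) & (
            c0 + t * np.cos(angle) >= 0
        ) & (c0 + t * np.cos(angle) < W)
        mask[rr[inside], cc[inside]] = True
    if not mask.any():
        mask[H // 2, :] = True
    return mask


def _point_mask(rng: np.random.Generator, shape, n_points: int) -> np.ndarray:
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    rr = rng.integers(0, H, n_points)
    cc = rng.integers(0, W, n_points)
    mask[rr, cc] = True
    return mask


def _large_water_mask(landscape: LandCoverGrid, water_code: int = 4) -> np.ndarray:
    """Largest connected water body, or the grid center if no water exists."""
    water = landscape.values == water_code
    if not water.any():
        m = np.zeros(landscape.shape, dtype=bool)
        m[landscape.shape[0] // 2, landscape.shape[1] // 2] = True
        return m
    labels, n = ndimage.label(water, structure=np.ones((3, 3), dtype=bool))
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def generate_drivers(
    spec: SyntheticSpec, landscape: LandCoverGrid, seed: int | None = None
) -> DriverStack:
    """Driver stack: distances to random line/point features, fractal DEM, slope."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 202)
    shape = spec.shape
    cs = spec.cell_size
    surfaces: dict[str, np.ndarray] = {}
    surfaces["distance_highway"] = distance_surface(_polyline_mask(rng, shape, 1), cs)
    surfaces["distance_railway"] = distance_surface(_polyline_mask(rng, shape, 1), cs)
    surfaces["distance_roads"] = distance_surface(_polyline_mask(rng, shape, 3), cs)
    surfaces["distance_town_centers"] = distance_surface(_point_mask(rng, shape, 8), cs)
    surfaces["distance_urban_centers"] = distance_surface(_point_mask(rng, shape, 2), cs)
    surfaces["distance_water"] = distance_surface(_large_water_mask(landscape), cs)
    # Fractal-ish DEM: sum of smoothed-noise octaves at decreasing amplitude.
    dem = np.zeros(shape)
    if spec.dem_roughness > 0:
        for octave, (sigma, amp) in enumerate([(20, 1.0), (8, 0.5), (3, 0.25)]):
            dem += amp * _smooth_noise(rng, shape, sigma)
        dem = (dem - dem.min()) / (dem.max() - dem.min() or 1.0)
        dem *= spec.dem_relief * spec.dem_roughness
    surfaces["elevation"] = dem
    surfaces["slope"] = slope_surface(dem, cs) if min(shape) >= 3 else np.zeros(shape)
    assert tuple(surfaces) == DRIVER_NAMES
    return DriverStack(surfaces, cs)


def generate_masks(
    spec: SyntheticSpec,
    landscape: LandCoverGrid,
    drivers: DriverStack,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Policy masks: permanent farmland and two conservation-zone grades.

    Permanent farmland: a smooth random half of current farmland cells.
    Conservation grade 1: within 500 m of the large water body; grade 2: the
    500-1500 m annulus.
    """
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 303)
    smooth = _smooth_noise(rng, spec.shape, max(spec.autocorr_length, 1.0))
    farmland = landscape.values == 1
    permanent = farmland & (smooth > np.median(smooth[farmland]) if farmland.any() else False)
    dw = drivers.surfaces["distance_water"]
    grade1 = dw <= 500.0
    grade2 = (dw > 500.0) & (dw <= 1500.0)
    return {
        "permanent_farmland": permanent,
        "conservation_grade1": grade1,
        "conservation_grade2": grade2,
    }


def _standardized_drivers(drivers: DriverStack) -> dict[str, np.ndarray]:
    out = {}
    for name in drivers.names:
        s = drivers.surfaces[name]
        std = s.std()
        out[name] = (s - s.mean()) / (std if std > 0 else 1.0)
    return out


def transition_probabilities_true(
    landscape: LandCoverGrid, drivers: DriverStack, spec: SyntheticSpec
) -> np.ndarray:
    """Exact per-cell transition probabilities of the generating model.

    Returns an (n_classes, H, W) array: layer j is P(next = class_j | cell).
    Model: softmax over targets j of base[i, j] + beta_j . x + eta * f_j,
    with x the standardized drivers and f_j the 3x3 neighborhood fraction of
    class j (computed without the center cell).
    """
    from .ca import neighborhood_factor

    codes = landscape.scheme.codes
    n = len(codes)
    x = _standardized_drivers(drivers)
    neigh = {c: neighborhood_factor(landscape, c, 3) for c in codes}
    H, W = landscape.shape
    util = np.zeros((n, H, W))
    lut = np.zeros(max(codes) + 1, dtype=np.int64)
    for k, c in enumerate(codes):
        lut[c] = k
    src_idx = lut[landscape.values]
    for jj, j_code in enumerate(codes):
        u = spec.base_logodds[src_idx, jj].astype(float)
        for driver, coef in spec.driver_coeffs.get(j_code, {}).items():
            u = u + coef * x[driver]
        u = u + spec.neighborhood_coeff * neigh[j_code]
        util[jj] = u
    util -= util.max(axis=0, keepdims=True)
    p = np.exp(util)
    p /= p.sum(axis=0, keepdims=True)
    return p


def evolve_landscape(
    landscape: LandCoverGrid,
    drivers: DriverStack,
    spec: SyntheticSpec,
    seed: int | None = None,
) -> tuple[LandCoverGrid, np.ndarray]:
    """Sample a later-date landscape from the ground-truth transition model.

    Returns the realized grid and the exact (n_classes, H, W) probability
    array it was sampled from, so tests can use closed-form expectations.
    """
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 404)
    probs = transition_probabilities_true(landscape, drivers, spec)
    cum = np.cumsum(probs, axis=0)
    u = rng.uniform(size=landscape.shape)
    idx = (u[None, :, :] > cum).sum(axis=0)
    values = np.asarray(landscape.scheme.codes)[idx]
    evolved = LandCoverGrid(
        values.astype(np.int64),
        landscape.cell_size,
        landscape.origin,
        landscape.nodata,
        landscape.scheme,
    )
    return evolved, probs


def make_world(spec: SyntheticSpec | None = None) -> dict:
    """Generate the full input bundle for an end-to-end run.

    Returns dict with: t1 / t2 land-cover grids, true transition
    probabilities, drivers, zones, and policy masks — all aligned and
    deterministic under ``spec.seed``.
    """
    spec = spec or SyntheticSpec()
    t1 = generate_landscape(spec)
    drivers = generate_drivers(spec, t1)
    t2, probs = evolve_landscape(t1, drivers, spec)
    zones = generate_zones(spec)
    masks = generate_masks(spec, t2, drivers)
    return {
        "spec": spec,
        "t1": t1,
        "t2": t2,
        "true_probs": probs,
        "drivers": drivers,
        "zones": zones,
        "masks": masks,
    }
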