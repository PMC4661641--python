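import numpy as np
import pytest

from landrisk.grid import ClassScheme, LandCoverGrid, ZoneGrid
from landrisk.synthetic import SyntheticSpec, make_world


@pytest.fixture(scope="session")
def small_world():
    """Deterministic 60x60 synthetic world shared by pipeline tests."""
    return make_world(SyntheticSpec(shape=(60, 60), seed=3))


@pytest.fixture
def two_class_scheme():
    return ClassScheme(codes=(1, 2), names=("a", "b"), vulnerability_grades=(1, 2))


def make_grid(values, cell_size=100.0, scheme=None, nodata=-9999):
    values = np.asarray(values, dtype=np.int64)
    if scheme is None:
        codes = tuple(sorted({int(v) for v in np.unique(values) if v != nodata}))
        scheme = ClassScheme(
            codes=codes,
            names=tuple(f"c{c}" for c in codes),
            vulnerability_grades=tuple(min(6, k + 1) for k in range(len(codes))),
        )
    return LandCoverGrid(values, cell_size, scheme=scheme, nodata=nodata)


@pytest.fixture
def grid_factory():
    return make_grid


def random_grid(rng, shape, n_classes=3, cell_size=100.0):
    values = rng.integers(1, n_classes + 1, size=shape)
    return make_grid(values, cell_size=cell_size)


@pytest.fixture
def random_grid_factory():
    return random_grid
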