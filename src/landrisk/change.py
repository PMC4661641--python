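"""Land-change accounting between two dates.

Cross-tabulates aligned categorical rasters into an area transition matrix
(hectares), then derives the standard change statistics: the dynamic degree
index (converted area as a percentage of total area over the period), net
change per class, row-stochastic transition probabilities, and conversion
summaries for a target class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import ClassScheme, EZHOU_SCHEME, LandCoverGrid, align_check

__all__ = [
    "TransitionMatrix",
    "cross_tabulate",
    "dynamic_degree",
    "dynamic_degree_per_class",
    "net_change",
    "transition_probabilities",
    "conversion_summary",
]


@dataclass
class TransitionMatrix:
    """n-by-n area matrix (ha): entry (i, j) is area moving from class i to class j."""

    area: np.ndarray
    scheme: ClassScheme = EZHOU_SCHEME
    from_date: str = ""
    to_date: str = ""

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        n = self.scheme.n_classes
        if self.area.shape != (n, n):
            raise ValueError(f"transition matrix must be {n}x{n}, got {self.area.shape}")
        if (self.area < 0).any():
            raise ValueError("transition areas must be non-negative")

    @property
    def total_area(self) -> float:
        return float(self.area.sum())

    def row_sums(self) -> np.ndarray:
        """Class areas at the start date."""
        return self.area.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        """Class areas at the end date."""
        return self.area.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        names = list(self.scheme.names)
        return pd.DataFrame(self.area, index=names, columns=names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        scheme: ClassScheme = EZHOU_SCHEME,
        from_date: str = "",
        to_date: str = "",
    ) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0)
        names = list(scheme.names)
        return cls(df.loc[names, names].to_numpy(), scheme, from_date, to_date)


def cross_tabulate(grid_t1: LandCoverGrid, grid_t2: LandCoverGrid) -> TransitionMatrix:
    """Cross-tabulate two aligned land-cover grids into an area matrix.

    Cells that are nodata at either date are excluded from all entries, so
    both marginals refer to the same set of cells and the grand total is the
    shared valid area.
    """
    align_check([grid_t1, grid_t2]).raise_if_failed()
    if grid_t1.scheme != grid_t2.scheme:
        raise ValueError("grids use different class schemes")
    scheme = grid_t1.scheme
    valid = grid_t1.valid_mask & grid_t2.valid_mask
    code_to_idx = {c: k for k, c in enumerate(scheme.codes)}
    lut = np.zeros(max(scheme.codes) + 1, dtype=np.int64)
    for c, k in code_to_idx.items():
        lut[c] = k
    i = lut[grid_t1.values[valid]]
    j = lut[grid_t2.values[valid]]
    n = scheme.n_classes
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n)
    return TransitionMatrix(counts * grid_t1.cell_area_ha, scheme)


def dynamic_degree(tm: TransitionMatrix) -> float:
    """Dynamic degree index: converted area / total area x 100 (percent).

    Equals 100 * (1 - trace / total); 0 for a fully persistent landscape,
    100 when every cell changes class.
    """
    total = tm.total_area
    if total <= 0:
        raise ValueError("dynamic_degree undefined for zero total area")
    changed = total - float(np.trace(tm.area))
    return changed / total * 100.0


def dynamic_degree_per_class(tm: TransitionMatrix) -> dict[int, float]:
    """Per-class variant: out-conversion of class i as a percent of its start area."""
    rows = tm.row_sums()
    out = {}
    for k, code in enumerate(tm.scheme.codes):
        if rows[k] > 0:
            out[code] = float((rows[k] - tm.area[k, k]) / rows[k] * 100.0)
        else:
            out[code] = float("nan")
    return out


def net_change(tm: TransitionMatrix) -> dict[int, float]:
    """Net gain (+) or loss (-) in hectares per class: column sum minus row sum."""
    delta = tm.col_sums() - tm.row_sums()
    return {code: float(delta[k]) for k, code in enumerate(tm.scheme.codes)}


def transition_probabilities(tm: TransitionMatrix) -> np.ndarray:
    """Row-stochastic one-step Markov matrix; absent classes self-transition."""
    rows = tm.row_sums()
    n = tm.scheme.n_classes
    probs = np.empty((n, n))
    for k in range(n):
        if rows[k] > 0:
            probs[k] = tm.area[k] / rows[k]
        else:
            probs[k] = 0.0
            probs[k, k] = 1.0
    return probs


def conversion_summary(
    tm: TransitionMatrix,
    to_class: int,
    from_classes: tuple[int, ...] | None = None,
) -> dict:
    """Summarize conversions into ``to_class`` from all other classes.

    Returns the total converted area (off-diagonal column sum, ha), the share
    of each source class in that total, and — if ``from_classes`` is given —
    the partial area from that subset with its share of the total.
    """
    j = tm.scheme.index_of(to_class)
    col = tm.area[:, j].copy()
    col[j] = 0.0
    total = float(col.sum())
    if total == 0:
        return {"total_ha": 0.0, "shares": {}, "subset_ha": 0.0, "subset_share": float("nan")}
    shares = {
        code: float(col[k] / total)
        for k, code in enumerate(tm.scheme.codes)
        if k != j
    }
    out = {"total_ha": total, "shares": shares}
    if from_classes is not None:
        idx = [tm.scheme.index_of(c) for c in from_classes]
        subset = float(col[idx].sum())
        out["subset_ha"] = subset
        out["subset_share"] = subset / total
    return out
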