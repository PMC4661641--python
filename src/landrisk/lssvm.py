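"""Least-squares SVM transition rules: per-transition suitability surfaces.

For every ordered class pair (i -> j) a binary LSSVM is trained on stratified
samples of observed conversions (positives: cells that made the transition
between the calibration dates; negatives: same-source cells that did not).
Training reduces to one dense linear (KKT) system

    [[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y]

with an RBF kernel K_mn = exp(-||x_m - x_n||^2 / (2 sigma^2)) on features
standardized with training-set statistics.  Decision values on the current
source-class cells are min-max mapped to a [0, 1] suitability surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .grid import DriverStack, LandCoverGrid, align_check

__all__ = [
    "SampleSet",
    "LSSVMModel",
    "SuitabilityStack",
    "stratified_sample",
    "train_lssvm",
    "predict_suitability",
    "evaluate_suitability",
    "build_suitability_stack",
]


@dataclass
class SampleSet:
    """Labeled driver vectors for one transition (i -> j)."""

    X: np.ndarray  # (n, n_drivers) raw (unstandardized) features
    y: np.ndarray  # (n,) labels in {+1, -1}
    rows: np.ndarray
    cols: np.ndarray
    transition: tuple[int, int]
    shortfall: bool = False  # fewer positives available than requested

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class LSSVMModel:
    """Solved LSSVM: support coefficients, bias, kernel spec, feature statistics."""

    alpha: np.ndarray
    b: float
    X_train: np.ndarray  # standardized training features
    gamma: float
    sigma: float
    feature_mean: np.ndarray
    feature_std: np.ndarray
    transition: tuple[int, int] = (0, 0)
    kkt_residual: float = 0.0

    def decision(self, X_raw: np.ndarray) -> np.ndarray:
        """f(x) = sum_m alpha_m K(x, x_m) + b on raw-feature inputs."""
        Xs = (X_raw - self.feature_mean) / self.feature_std
        out = np.empty(len(Xs))
        # Chunked kernel evaluation keeps memory bounded on full rasters.
        step = 4096
        for s in range(0, len(Xs), step):
            d2 = cdist(Xs[s : s + step], self.X_train, "sqeuclidean")
            out[s : s + step] = np.exp(-d2 / (2 * self.sigma**2)) @ self.alpha + self.b
        return out


@dataclass
class SuitabilityStack:
    """[0, 1] suitability surface per transition, aligned to the land-cover grid."""

    surfaces: dict[tuple[int, int], np.ndarray]
    shape: tuple[int, int]

    def get(self, i: int, j: int) -> np.ndarray:
        """Surface for transition i -> j; untrained transitions fall back to 0."""
        if (i, j) in self.surfaces:
            return self.surfaces[(i, j)]
        return np.zeros(self.shape)


def stratified_sample(
    grid_t1: LandCoverGrid,
    grid_t2: LandCoverGrid,
    drivers: DriverStack,
    n_per_type: int = 500,
    seed: int = 0,
    include_persistence: bool = True,
) -> dict[tuple[int, int], SampleSet]:
    """Stratified samples of observed transitions, balanced 1:1 with negatives.

    For each transition i -> j with observed occurrences: up to ``n_per_type``
    positive cells (t1 = i, t2 = j) and an equal number of negatives
    (t1 = i, t2 != j), drawn uniformly without replacement under ``seed``.
    Transitions with fewer occurrences than requested take all and are
    flagged; transitions never observed yield no sample set.
    """
    align_check([grid_t1, grid_t2, drivers]).raise_if_failed()
    rng = np.random.default_rng(seed)
    out: dict[tuple[int, int], SampleSet] = {}
    valid = grid_t1.valid_mask & grid_t2.valid_mask
    codes = grid_t1.scheme.codes
    for i in codes:
        src = (grid_t1.values == i) & valid
        for j in codes:
            if i == j and not include_persistence:
                continue
            pos_mask = src & (grid_t2.values == j)
            neg_mask = src & (grid_t2.values != j)
            n_pos_avail = int(pos_mask.sum())
            if n_pos_avail == 0:
                continue
            n_take = min(n_per_type, n_pos_avail)
            shortfall = n_take < n_per_type
            if shortfall:
                warnings.warn(
                    f"transition {i}->{j}: only {n_pos_avail} occurrences "
                    f"(requested {n_per_type})",
                    stacklevel=2,
                )
            n_neg = min(n_take, int(neg_mask.sum()))
            if n_neg == 0:
                continue
            pr, pc = np.nonzero(pos_mask)
            nr, nc = np.nonzero(neg_mask)
            pi = rng.choice(len(pr), size=n_take, replace=False)
            ni = rng.choice(len(nr), size=n_neg, replace=False)
            rows = np.concatenate([pr[pi], nr[ni]])
            cols = np.concatenate([pc[pi], nc[ni]])
            y = np.concatenate([np.ones(n_take), -np.ones(n_neg)])
            X = drivers.feature_matrix(rows, cols)
            out[(i, j)] = SampleSet(X, y, rows, cols, (i, j), shortfall)
    return out


def train_lssvm(
    samples: SampleSet, gamma: float = 10.0, sigma: float | None = None
) -> LSSVMModel:
    """Solve the LSSVM KKT system for one transition's sample set.

    ``sigma`` defaults to sqrt(d / 2) for d features — the standard
    dimension-scaled RBF width (kernel exp(-||dx||^2 / d)), which keeps the
    kernel informative as the feature count grows; a fixed width that
    ignores dimension collapses toward a diagonal kernel in 8-D.
    """
    if samples.n < 2 or len(np.unique(samples.y)) < 2:
        raise ValueError("training needs at least two samples with both labels")
    if sigma is None:
        sigma = float(np.sqrt(samples.X.shape[1] / 2.0))
    mean = samples.X.mean(axis=0)
    std = samples.X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (samples.X - mean) / std
    n = samples.n
    d2 = cdist(Xs, Xs, "sqeuclidean")
    K = np.exp(-d2 / (2 * sigma**2))
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], samples.y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular LSSVM system for {samples.transition}: {e}") from e
    residual = float(np.abs(A @ sol - rhs).max())
    model = LSSVMModel(
        alpha=sol[1:],
        b=float(sol[0]),
        X_train=Xs,
        gamma=gamma,
        sigma=sigma,
        feature_mean=mean,
        feature_std=std,
        transition=samples.transition,
        kkt_residual=residual,
    )
    return model


def predict_suitability(
    model: LSSVMModel,
    drivers: DriverStack,
    source_mask: np.ndarray,
    squash: str = "minmax",
) -> np.ndarray:
    """Suitability surface on the source-class cells, zero elsewhere.

    Decision values on the mask are mapped to [0, 1] by min-max (default) or
    a logistic squash; a constant decision surface maps to 0.5.
    """
    surface = np.zeros(source_mask.shape)
    if not source_mask.any():
        warnings.warn("predict_suitability: empty source mask", stacklevel=2)
        return surface
    rows, cols = np.nonzero(source_mask)
    f = model.decision(drivers.feature_matrix(rows, cols))
    if squash == "minmax":
        lo, hi = f.min(), f.max()
        vals = np.full_like(f, 0.5) if hi == lo else (f - lo) / (hi - lo)
    elif squash == "logistic":
        vals = 1.0 / (1.0 + np.exp(-f))
    else:
        raise ValueError(f"unknown squash {squash!r}")
    surface[rows, cols] = vals
    return surface


def evaluate_suitability(model: LSSVMModel, held_out: SampleSet) -> float:
    """Ranking quality (ROC AUC) of the decision function on held-out samples."""
    y = held_out.y
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined on a one-class held-out set")
    f = model.decision(held_out.X)
    r = rankdata(f)
    n_pos = int((y > 0).sum())
    n_neg = len(y) - n_pos
    auc = (r[y > 0].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def build_suitability_stack(
    grid_t1: LandCoverGrid,
    grid_t2: LandCoverGrid,
    drivers: DriverStack,
    current: LandCoverGrid | None = None,
    n_per_type: int = 500,
    seed: int = 0,
    gamma: float = 10.0,
    sigma: float | None = None,
) -> tuple[SuitabilityStack, dict[tuple[int, int], LSSVMModel]]:
    """Calibrate all transition models on (t1, t2) and predict suitability.

    Suitability surfaces are evaluated on ``current`` (default: ``grid_t2``,
    the later calibration date, which is the usual simulation start).
    """
    state = grid_t2 if current is None else current
    sample_sets = stratified_sample(grid_t1, grid_t2, drivers, n_per_type, seed)
    models: dict[tuple[int, int], LSSVMModel] = {}
    surfaces: dict[tuple[int, int], np.ndarray] = {}
    for (i, j), ss in sample_sets.items():
        if len(np.unique(ss.y)) < 2:
            continue
        model = train_lssvm(ss, gamma=gamma, sigma=sigma)
        models[(i, j)] = model
        source = (state.values == i) & state.valid_mask
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            surfaces[(i, j)] = predict_suitability(model, drivers, source)
    return SuitabilityStack(surfaces, state.shape), models
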