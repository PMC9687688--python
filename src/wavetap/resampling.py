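"""Class balancing by SMOTE and min-max feature scaling.

SMOTE (Synthetic Minority Oversampling Technique) balances a two-class
feature matrix by interpolating new minority-class points: for a minority
sample ``x`` and one of its k nearest minority neighbours ``x_k`` (Euclidean
distance), a synthetic point is drawn uniformly on the segment between them,

    x' = x + u * (x_k - x),   u ~ Uniform(0, 1).

Synthetic rows are therefore convex combinations of real minority rows and
never leave the minority class's per-coordinate bounding box.  A
``paper_formula`` switch reproduces the alternative published form
``x' = x + u * |x - x_k|``, whose element-wise absolute value biases offsets
positive; it is kept only for comparison.

Oversampling runs on raw (pre-scaling) features; min-max scaling to [0, 1]
follows it in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler

from .tappy_io import FeatureMatrix

__all__ = ["SmoteConfig", "smote_oversample", "minmax_scale", "apply_minmax"]


@dataclass
class SmoteConfig:
    """Oversampling parameters.

    ``k_neighbors`` must be smaller than the minority class size.  The
    default target balances the classes exactly (minority count grows to the
    majority count).
    """

    k_neighbors: int = 5
    seed: int = 42
    target: int | None = None  # synthetic+real minority count; None = match majority


def smote_oversample(matrix: FeatureMatrix, config: SmoteConfig | None = None) -> FeatureMatrix:
    """Append synthetic minority rows until the class counts meet the target.

    Synthetic rows are appended after all real rows, flagged with
    ``provenance == "synthetic"``, and tagged with subject ids of the form
    ``smote_<i>``.  Deterministic given ``config.seed``.

    Raises
    ------
    ValueError
        If the matrix does not contain exactly two classes, or the minority
        class is not larger than ``k_neighbors``.
    """
    config = config or SmoteConfig()
    labels = matrix.labels.astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"SMOTE needs exactly two classes, got {classes.tolist()}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    target = n_maj if config.target is None else int(config.target)
    n_new = int(target - n_min)
    if n_new <= 0:
        return matrix  # already balanced (or target met): no-op
    if n_min <= config.k_neighbors:
        raise ValueError(
            f"minority class size {n_min} must exceed k_neighbors={config.k_neighbors}"
        )

    X_min = matrix.values[labels == minority]
    k = config.k_neighbors
    # +1 because each point's nearest neighbour is itself
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neigh_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, n_min, size=n_new)
    picks = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)

    base = X_min[seeds]
    neigh = X_min[neigh_idx[seeds, picks]]
    synthetic = base + u[:, None] * (neigh - base)

    new_labels = np.array([minority] * n_new, dtype=object)
    new_ids = np.array([f"smote_{i}" for i in range(n_new)], dtype=object)
    return FeatureMatrix(
        values=np.vstack([matrix.values, synthetic]),
        column_names=list(matrix.column_names),
        labels=np.concatenate([matrix.labels, new_labels]),
        subject_ids=np.concatenate([matrix.subject_ids, new_ids]),
        provenance=np.concatenate(
            [matrix.provenance, np.array(["synthetic"] * n_new, dtype=object)]
        ),
    )


def paper_formula_oversample(
    matrix: FeatureMatrix, config: SmoteConfig | None = None
) -> FeatureMatrix:
    """SMOTE variant using the absolute-offset form ``x + u * |x - x_k|``.

    Kept for comparison only: the element-wise absolute value makes every
    offset non-negative, so synthetic points drift toward larger feature
    values instead of staying on the interpolation segment.
    """
    config = config or SmoteConfig()
    balanced = smote_oversample(matrix, config)
    n_real = matrix.n_subjects
    if balanced.n_subjects == n_real:
        return balanced
    # Recompute offsets with the same draws but absolute displacement.
    labels = matrix.labels.astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    minority = classes[np.argmin(counts)]
    X_min = matrix.values[labels == minority]
    k = config.k_neighbors
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neigh_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    n_new = balanced.n_subjects - n_real
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, X_min.shape[0], size=n_new)
    picks = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    base = X_min[seeds]
    neigh = X_min[neigh_idx[seeds, picks]]
    balanced.values[n_real:] = base + u[:, None] * np.abs(base - neigh)
    return balanced


def minmax_scale(matrix: FeatureMatrix) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Affinely map every column onto [0, 1]; constant columns map to 0.

    Returns the scaled matrix plus the per-column ``(min, max)`` arrays so
    the same transform can be reapplied to new data with
    :func:`apply_minmax`.
    """
    if matrix.n_subjects < 2:
        raise ValueError("min-max scaling needs at least 2 rows")
    scaler = MinMaxScaler().fit(matrix.values)
    col_min, col_max = scaler.data_min_, scaler.data_max_
    scaled = apply_minmax(matrix.values, col_min, col_max)
    out = FeatureMatrix(
        values=scaled,
        column_names=list(matrix.column_names),
        labels=matrix.labels.copy(),
        subject_ids=matrix.subject_ids.copy(),
        provenance=matrix.provenance.copy(),
    )
    return out, col_min, col_max


def apply_minmax(values: np.ndarray, col_min: np.ndarray, col_max: np.ndarray) -> np.ndarray:
    """Apply stored per-column (min, max) parameters to a value matrix."""
    rng_ = np.asarray(col_max, dtype=float) - np.asarray(col_min, dtype=float)
    safe = np.where(rng_ == 0.0, 1.0, rng_)
    return (np.asarray(values, dtype=float) - col_min) / safe
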