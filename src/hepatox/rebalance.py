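"""SMOTE oversampling of the minority class.

Synthetic minority points are drawn on the segment between a randomly
chosen minority sample and one of its k nearest minority-class neighbors
(Euclidean distance, uniform interpolation factor in [0, 1]).  Intended for
training folds only — oversampling validation data leaks synthetic copies
of held-out structure into the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass
class SmoteConfig:
    """``target_ratio`` is the minority/majority count ratio after
    augmentation (1.0 = parity)."""

    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must be in (0, 1]")


def _plan(y: np.ndarray):
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(
            f"SMOTE requires exactly two classes, got {list(classes)}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    return minority, int(n_min), int(n_maj)


def smote_oversample(features: np.ndarray, labels: np.ndarray,
                     config: SmoteConfig = SmoteConfig()
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Append synthetic minority rows until
    minority/majority >= ``target_ratio``.

    Original rows are returned unchanged (synthetic rows appended after
    them); deterministic for a fixed config seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    minority, n_min, n_maj = _plan(y)
    if n_min < 2:
        raise ValueError(
            "SMOTE needs at least 2 minority samples (no neighbor exists)")
    n_new = int(round(config.target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return X.copy(), y.copy()
    k = config.k_neighbors
    if n_min <= k:
        warnings.warn(
            f"minority count {n_min} <= k_neighbors {k}; "
            f"reducing k to {n_min - 1}", stacklevel=2)
        k = n_min - 1
    minority_rows = X[y == minority]
    # +1 because each point is its own nearest neighbor
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority_rows)
    neighbors = nn.kneighbors(minority_rows, return_distance=False)[:, 1:]
    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.random(size=(n_new, 1))
    anchors = minority_rows[base]
    targets = minority_rows[neighbors[base, pick]]
    synthetic = anchors + u * (targets - anchors)
    X_aug = np.vstack([X, synthetic])
    y_aug = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_aug, y_aug


def smote_oversample_multilabel(features: np.ndarray, label_matrix: np.ndarray,
                                config: SmoteConfig = SmoteConfig()
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Multi-endpoint variant: the minority class is 'any endpoint
    positive'; each synthetic row inherits the full label triple of its
    anchor sample (interpolated labels are not meaningful)."""
    X = np.asarray(features, dtype=float)
    Y = np.asarray(label_matrix)
    y_any = Y.max(axis=1)
    minority, n_min, n_maj = _plan(y_any)
    if n_min < 2:
        raise ValueError(
            "SMOTE needs at least 2 minority samples (no neighbor exists)")
    n_new = int(round(config.target_ratio * n_maj)) - n_min
    if n_new <= 0:
        return X.copy(), Y.copy()
    k = min(config.k_neighbors, n_min - 1)
    if k < config.k_neighbors:
        warnings.warn(
            f"minority count {n_min} <= k_neighbors {config.k_neighbors}; "
            f"reducing k to {k}", stacklevel=2)
    mask = y_any == minority
    minority_rows = X[mask]
    minority_labels = Y[mask]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority_rows)
    neighbors = nn.kneighbors(minority_rows, return_distance=False)[:, 1:]
    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.random(size=(n_new, 1))
    synthetic = minority_rows[base] + u * (
        minority_rows[neighbors[base, pick]] - minority_rows[base])
    return (np.vstack([X, synthetic]),
            np.vstack([Y, minority_labels[base]]))
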