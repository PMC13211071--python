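"""Synthetic minority oversampling (SMOTE) for the training folds.

Classic k-nearest-neighbour interpolation: each synthetic minority sample
lies uniformly at random on the segment between a real minority sample and
one of its k nearest minority neighbours. Applied to training rows only —
test rows are never touched.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary training set by oversampling the minority class.

    Returns (X_res, y_res) with the original rows first, followed by the
    synthetic minority rows. Already-balanced input passes through
    unchanged. With a single minority sample no neighbours exist, so the
    sample is duplicated instead of interpolated.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects exactly two classes in the training set")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X, y

    X_min = X[y == minority]
    if len(X_min) == 1:
        synth = np.repeat(X_min, n_needed, axis=0)
    else:
        k = min(k_neighbors, len(X_min) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        neighbour_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
        base = rng.integers(len(X_min), size=n_needed)
        picked = neighbour_idx[base, rng.integers(k, size=n_needed)]
        gamma = rng.random((n_needed, 1))
        synth = X_min[base] + gamma * (X_min[picked] - X_min[base])
    X_res = np.vstack([X, synth])
    y_res = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_res, y_res
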