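"""Sampling-based Shapley feature attributions for fitted models.

Monte-Carlo permutation estimator of Shapley values under the marginal
(interventional) expectation: for each sampled feature permutation, start
from a background row and switch features to the explained row one at a
time in permutation order; the change in model output as feature j
switches is its marginal contribution. Averaging over permutations and
background draws gives an unbiased estimate of the Shapley value.

Two exact properties of the estimator are worth noting. The contributions
telescope, so for every sample the attributions sum exactly to
f(x) − mean over sampled backgrounds of f(background) (local accuracy
holds at any number of permutations). And a feature the model output never
depends on — a constant column, say — receives exactly zero attribution.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def permutation_shap_values(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 32,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Shapley attribution matrix, shape (n_samples, n_features).

    ``predict`` maps an (m, n_features) array to m scalar outputs (for a
    classifier, the positive-class probability). ``background`` supplies
    the reference distribution; one row is drawn per (sample, permutation).
    Deterministic under a fixed ``rng``.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    n, m = X.shape
    phi = np.zeros((n, m), dtype=float)
    for _ in range(n_permutations):
        order = rng.permutation(m)
        b_rows = background[rng.integers(len(background), size=n)]
        # build the chain of hybrids: step 0 is pure background, step m is x
        chain = np.empty((m + 1, n, m), dtype=float)
        z = b_rows.copy()
        chain[0] = z
        for step, j in enumerate(order, start=1):
            z = z.copy()
            z[:, j] = X[:, j]
            chain[step] = z
        preds = predict(chain.reshape((m + 1) * n, m)).reshape(m + 1, n)
        deltas = np.diff(preds, axis=0)  # (m, n): contribution at each step
        for step, j in enumerate(order):
            phi[:, j] += deltas[step]
    return phi / n_permutations


def exact_shap_values(
    predict: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
) -> np.ndarray:
    """Exact Shapley values for one row by full subset enumeration.

    v(S) is the marginal expectation of the model output with features in
    S taken from x and the rest from the background rows. Exponential in
    the number of features — an oracle for small problems, not a tool.
    """
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    m = len(x)
    if m > 16:
        raise ValueError("subset enumeration is intractable beyond 16 features")
    from itertools import combinations
    from math import factorial

    def value(subset: tuple[int, ...]) -> float:
        z = background.copy()
        for j in subset:
            z[:, j] = x[j]
        return float(np.mean(predict(z)))

    cache: dict[tuple[int, ...], float] = {}

    def v(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = value(subset)
        return cache[subset]

    phi = np.zeros(m)
    others = list(range(m))
    for j in range(m):
        rest = [k for k in others if k != j]
        for size in range(m):
            weight = factorial(size) * factorial(m - size - 1) / factorial(m)
            for subset in combinations(rest, size):
                phi[j] += weight * (v(tuple(sorted(subset + (j,)))) - v(subset))
    return phi
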