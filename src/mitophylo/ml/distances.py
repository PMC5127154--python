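"""Pairwise maximum-likelihood distances under a fixed GTR+G+I model.

The distance between two rows is the branch length of the two-taxon tree
maximizing the likelihood of their joint site counts, capped at a
configurable maximum.  Sites where either taxon is missing are ignored;
a pair must share at least one scored column.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .gtr import GTRGIParams, transition_matrix

MAX_DISTANCE = 5.0


def _joint_counts(codes_a, codes_b, weights) -> np.ndarray:
    """Weighted 4x4 joint base counts over columns observed in both rows."""
    both = (codes_a < 4) & (codes_b < 4)
    counts = np.zeros((4, 4))
    np.add.at(counts, (codes_a[both], codes_b[both]), weights[both])
    return counts


def _pair_loglik(counts: np.ndarray, params: GTRGIParams, eigen, rates) -> callable:
    pi = np.array(params.base_freqs)
    w = params.category_weights()
    inv = np.diag(params.p_inv * pi)

    def f(t: float) -> float:
        P = sum(wk * transition_matrix(params, t, rk, eigen)
                for wk, rk in zip(w, rates))
        joint = pi[:, None] * P + inv
        return float((counts * np.log(np.clip(joint, 1e-300, None))).sum())

    return f


def ml_distance(engine, taxon_a: str, taxon_b: str,
                params: GTRGIParams, max_dist: float = MAX_DISTANCE) -> float:
    """ML distance between two taxa of a :class:`PruningEngine`'s alignment."""
    codes_a = engine.patterns[engine._row[taxon_a]]
    codes_b = engine.patterns[engine._row[taxon_b]]
    counts = _joint_counts(codes_a, codes_b, engine.weights)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"{taxon_a} and {taxon_b} share no scored columns")
    if np.trace(counts) == total:
        return 0.0
    eigen = params.eigen()
    rates = params.category_rates()
    f = _pair_loglik(counts, params, eigen, rates)
    res = minimize_scalar(lambda t: -f(t), bounds=(1e-8, max_dist),
                          method="bounded", options={"xatol": 1e-8})
    return float(res.x)


def ml_distance_matrix(engine, params: GTRGIParams,
                       max_dist: float = MAX_DISTANCE
                       ) -> tuple[list[str], np.ndarray]:
    taxa = list(engine.taxa)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_distance(engine, taxa[i], taxa[j],
                                            params, max_dist)
    return taxa, D
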