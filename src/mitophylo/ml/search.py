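"""Branch-length / model-parameter optimization and NNI topology search.

``optimize`` alternates (a) per-edge Brent branch-length passes and
(b) quasi-Newton optimization of the substitution-model parameters on
unconstrained transforms (log exchangeabilities with GT pinned to 1,
softmax base frequencies, log gamma shape, logit p_inv), stopping when a
round improves the log-likelihood by less than ``tol``.  The trace is
monotone: parameter proposals are only accepted when they improve.

``nni_search`` hill-climbs over nearest-neighbor interchanges: both
rearrangements of every internal edge are scored by re-optimizing the
central branch against cached conditionals, the best strictly-improving
move is applied, branch lengths are re-smoothed, and the loop repeats to a
local optimum.  Deterministic given inputs and the (postorder) edge
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ..trees import Node, PhyloTree
from .gtr import GTRGIParams
from .likelihood import BRANCH_MAX, BRANCH_MIN, BRENT_XTOL, PruningEngine


@dataclass
class SearchSettings:
    tol: float = 1e-4
    max_rounds: int = 20
    branch_sweeps: int = 1
    optimize_exchangeabilities: bool = True
    optimize_freqs: bool = True
    optimize_alpha: bool = True
    optimize_pinv: bool = True
    max_nni_rounds: int = 50


def _as_engine(data) -> PruningEngine:
    return data if isinstance(data, PruningEngine) else PruningEngine(data)


# ------------------------------------------------------- model-parameter fit
_LOGS_BOUND = 7.0


def _pack(params: GTRGIParams, s: SearchSettings) -> np.ndarray:
    theta = []
    if s.optimize_exchangeabilities:
        ex = params.normalized().exchangeabilities
        theta += [np.log(max(x, 1e-3)) for x in ex[:5]]
    if s.optimize_freqs:
        f = np.array(params.base_freqs)
        theta += list(np.log(f[:3] / f[3]))
    if s.optimize_alpha and params.n_rate_categories > 1:
        theta.append(np.log(params.gamma_shape))
    if s.optimize_pinv:
        p = min(max(params.p_inv, 1e-4), 0.98)
        theta.append(np.log(p / (1 - p)))
    return np.array(theta)


def _unpack(theta: np.ndarray, params: GTRGIParams, s: SearchSettings
            ) -> GTRGIParams:
    theta = np.clip(theta, -_LOGS_BOUND, _LOGS_BOUND)
    i = 0
    kw = {}
    if s.optimize_exchangeabilities:
        kw["exchangeabilities"] = tuple(np.exp(theta[i:i + 5])) + (1.0,)
        i += 5
    if s.optimize_freqs:
        z = np.concatenate([theta[i:i + 3], [0.0]])
        f = np.exp(z)
        kw["base_freqs"] = tuple(f / f.sum())
        i += 3
    if s.optimize_alpha and params.n_rate_categories > 1:
        kw["gamma_shape"] = float(np.clip(np.exp(theta[i]), 0.02, 100.0))
        i += 1
    if s.optimize_pinv:
        kw["p_inv"] = float(1.0 / (1.0 + np.exp(-theta[i])))
        i += 1
    return replace(params, **kw)


def fit_model_params(engine: PruningEngine, tree: PhyloTree,
                     params: GTRGIParams, settings: SearchSettings
                     ) -> tuple[GTRGIParams, float]:
    """Maximize logL over the substitution-model parameters at a fixed tree.
    Returns (params, logL); never worse than the starting configuration."""
    if settings.optimize_pinv and params.p_inv == 0.0:
        params = replace(params, p_inv=0.02)  # give the optimizer a foothold
    theta0 = _pack(params, settings)
    if theta0.size == 0:
        return params, engine.loglik(tree, params)
    start_ll = engine.loglik(tree, params)

    def objective(theta: np.ndarray) -> float:
        try:
            cand = _unpack(theta, params, settings)
            return -engine.loglik(tree, cand)
        except (ValueError, FloatingPointError):
            return 1e12

    res = minimize(objective, theta0, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-9})
    if -res.fun > start_ll:
        return _unpack(res.x, params, settings), float(-res.fun)
    return params, start_ll


# ----------------------------------------------------------------- optimize
def optimize(tree: PhyloTree, data, params: GTRGIParams,
             settings: SearchSettings | None = None
             ) -> tuple[PhyloTree, GTRGIParams, float]:
    """Coordinate ascent: branch lengths (Brent per edge) alternating with
    model parameters, until the round improvement drops below tol."""
    settings = settings or SearchSettings()
    engine = _as_engine(data)
    tree = tree.copy()
    for node in tree.postorder():
        if node.parent is not None and (node.length is None or node.length < BRANCH_MIN):
            node.length = max(node.length or 0.0, BRANCH_MIN)
    current = engine.loglik(tree, params)
    if not np.isfinite(current):
        raise ValueError("non-finite starting log-likelihood; check the "
                         "alignment for empty or all-missing rows")
    for _ in range(settings.max_rounds):
        before = current
        current = engine.optimize_branch_lengths(
            tree, params, sweeps=settings.branch_sweeps, tol=settings.tol)
        params, current = fit_model_params(engine, tree, params, settings)
        if current - before < settings.tol:
            break
    return tree, params, current


# --------------------------------------------------------------- NNI search
def _internal_edges(tree: PhyloTree) -> list[int]:
    """Indices (into the postorder node list) of internal non-root nodes."""
    nodes = list(tree.postorder())
    return [i for i, n in enumerate(nodes)
            if n.children and n.parent is not None and len(n.children) == 2]


def _apply_nni(tree: PhyloTree, edge_idx: int, alternative: int) -> tuple[PhyloTree, Node]:
    """Copy the tree and perform one of the two NNIs around an internal
    edge: swap one child of the edge's lower node with the lower node's
    sibling.  Subtrees keep their own branch lengths."""
    cand = tree.copy()
    nodes = list(cand.postorder())
    v = nodes[edge_idx]
    u = v.parent
    sib = next(c for c in u.children if c is not v)
    moved = v.children[1 - alternative]  # alt 0 swaps child B, alt 1 child A
    v.children[v.children.index(moved)] = sib
    u.children[u.children.index(sib)] = moved
    sib.parent, moved.parent = v, u
    v.support = None  # the central split changed
    return cand, v


def _optimize_edges_near(engine: PruningEngine, tree: PhyloTree,
                         params: GTRGIParams, v: Node) -> float:
    """One exact coordinate pass over the edges adjacent to an NNI around
    ``v`` (the central edge, its endpoints' child edges and the edge above
    the upper endpoint); returns the resulting full logL."""
    u = v.parent
    targets = [v] + list(v.children) + [c for c in u.children if c is not v]
    if u.parent is not None:
        targets.append(u)
    current = None
    for node in targets:
        f = engine._edge_loglik_fn(tree, params, node)
        res = minimize_scalar(lambda t: -f(t), bounds=(BRANCH_MIN, BRANCH_MAX),
                              method="bounded", options={"xatol": BRENT_XTOL})
        t0 = max(node.length or BRANCH_MIN, BRANCH_MIN)
        if -res.fun > f(t0):
            node.length = float(res.x)
            current = -res.fun
        else:
            current = f(t0)
    return current


def nni_search(tree: PhyloTree, data, params: GTRGIParams,
               settings: SearchSettings | None = None
               ) -> tuple[PhyloTree, float]:
    """NNI hill-climb from an optimized starting tree; returns the local
    optimum and its logL (never worse than the input).

    Candidates are first scored cheaply by re-optimizing only the central
    (swapped) edge; if no candidate improves, the top-scoring few are
    re-scored with a local pass over all edges adjacent to the swap before
    the search concedes a local optimum."""
    settings = settings or SearchSettings()
    engine = _as_engine(data)
    tree = tree.copy()
    current = engine.optimize_branch_lengths(tree, params, sweeps=1,
                                             tol=settings.tol)
    for _ in range(settings.max_nni_rounds):
        scored = []
        for edge_idx in _internal_edges(tree):
            for alt in (0, 1):
                cand, v = _apply_nni(tree, edge_idx, alt)
                f = engine._edge_loglik_fn(cand, params, v)
                res = minimize_scalar(lambda t: -f(t),
                                      bounds=(BRANCH_MIN, BRANCH_MAX),
                                      method="bounded",
                                      options={"xatol": BRENT_XTOL})
                v.length = float(res.x)
                scored.append((-res.fun, cand, v))
        scored.sort(key=lambda x: x[0], reverse=True)
        accepted = None
        if scored and scored[0][0] > current + settings.tol:
            accepted = (scored[0][0], scored[0][1])
        else:
            for quick_ll, cand, v in scored[:3]:
                refined = _optimize_edges_near(engine, cand, params, v)
                if refined > current + settings.tol:
                    accepted = (refined, cand)
                    break
        if accepted is None:
            break
        tree = accepted[1]
        current = engine.optimize_branch_lengths(tree, params, sweeps=1,
                                                 tol=settings.tol)
    return tree, current
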