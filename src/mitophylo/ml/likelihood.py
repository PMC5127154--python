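"""Felsenstein pruning under GTR+G+I with site-pattern compression.

Likelihoods are computed over unique site patterns with multiplicity
weights.  Gaps, N and '?' are missing data (partial likelihood of ones, not
a fifth state).  The site likelihood mixes the invariant class (rate 0,
weight p_inv, nonzero only for constant-compatible patterns) with k
discrete-gamma categories.  Per-node rescaling keeps everything finite for
large trees and long alignments.

Branch lengths are optimized one edge at a time by Brent search on the
exact single-edge likelihood: with the post-order (subtree) and pre-order
(rest-of-tree) conditionals cached, the log-likelihood as a function of one
branch length costs O(patterns x states) per evaluation.  Caches are
refreshed before each edge so every accepted update is a true coordinate
ascent step and the log-likelihood never decreases.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from ..trees import Node, PhyloTree
from .gtr import GTRGIParams, transition_matrix

#: nucleotide codes; everything else (gap, N, ?) is missing = 4
CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_TIP = np.vstack([np.eye(4), np.ones(4)])  # row 4 = missing data

BRANCH_MIN = 1e-8
BRANCH_MAX = 10.0
BRENT_XTOL = 1e-6
_SCALE_FLOOR = 1e-300


def encode_rows(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    taxa = list(rows)
    L = len(next(iter(rows.values())))
    codes = np.full((len(taxa), L), 4, dtype=np.int8)
    for i, t in enumerate(taxa):
        seq = rows[t]
        if len(seq) != L:
            raise ValueError(f"{t}: row length {len(seq)} != {L}")
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for base, code in CODE.items():
            codes[i, arr == ord(base)] = code
    return taxa, codes


class PruningEngine:
    """Pattern-compressed likelihood calculator for one alignment."""

    def __init__(self, data, weights: np.ndarray | None = None):
        if hasattr(data, "matrix") and hasattr(data, "taxa"):  # CodonSupermatrix
            rows = {t: data.matrix[t] for t in data.taxa}
        else:
            rows = dict(data)
        if not rows:
            raise ValueError("empty alignment")
        self.taxa, codes = encode_rows(rows)
        self.n_sites = codes.shape[1]
        patterns, inverse, counts = np.unique(
            codes, axis=1, return_inverse=True, return_counts=True)
        self.patterns = np.ascontiguousarray(patterns)
        self.pattern_index = inverse.ravel()
        self.weights = counts.astype(float) if weights is None else weights
        self._row = {t: i for i, t in enumerate(self.taxa)}
        # invariant-class compatibility: pattern p can be constant in state x
        obs = self.patterns[:, :, None] == np.arange(4)[None, None, :]
        missing = (self.patterns == 4)[:, :, None]
        self.inv_compat = np.all(obs | missing, axis=0)  # (P, 4) bool

    # ------------------------------------------------------------ bootstrap
    def resampled(self, rng: np.random.Generator, unit: str = "column"
                  ) -> "PruningEngine":
        """Engine for one nonparametric bootstrap replicate: resample the
        alignment's columns (or codon triplets) with replacement, expressed
        as new pattern weights."""
        L = self.n_sites
        if unit == "codon":
            if L % 3:
                raise ValueError("codon resampling needs length divisible by 3")
            starts = rng.integers(0, L // 3, size=L // 3) * 3
            cols = (starts[:, None] + np.arange(3)).ravel()
        elif unit == "column":
            cols = rng.integers(0, L, size=L)
        else:
            raise ValueError(f"unknown resampling unit {unit!r}")
        w = np.bincount(self.pattern_index[cols],
                        minlength=self.patterns.shape[1]).astype(float)
        keep = w > 0
        new = object.__new__(PruningEngine)
        new.taxa = self.taxa
        new.n_sites = L
        new.patterns = self.patterns[:, keep]
        new.pattern_index = None
        new.weights = w[keep]
        new._row = self._row
        new.inv_compat = self.inv_compat[keep]
        return new

    def subset(self, taxa: list[str]) -> "PruningEngine":
        rows_idx = [self._row[t] for t in taxa]
        sub = self.patterns[rows_idx]
        new = object.__new__(PruningEngine)
        new.taxa = list(taxa)
        new.n_sites = self.n_sites
        new.patterns = sub
        new.pattern_index = None
        new.weights = self.weights
        new._row = {t: i for i, t in enumerate(taxa)}
        obs = sub[:, :, None] == np.arange(4)[None, None, :]
        missing = (sub == 4)[:, :, None]
        new.inv_compat = np.all(obs | missing, axis=0)
        return new

    # ----------------------------------------------------------- likelihood
    def _check_tree(self, tree: PhyloTree) -> None:
        missing = set(tree.leaf_names()) - set(self.taxa)
        if missing:
            raise ValueError(f"tree leaves absent from alignment: {sorted(missing)}")

    def _tip_partial(self, name: str) -> np.ndarray:
        return _TIP[self.patterns[self._row[name]]]

    def _post_pass(self, tree: PhyloTree, params: GTRGIParams, eigen, rates):
        """Post-order conditionals.  Returns (post, scale, D, Dscale) keyed
        by (category, id(node)); D is the message a child sends its parent
        (already propagated through the child's branch)."""
        post, scale, D, Dscale = {}, {}, {}, {}
        nodes = list(tree.postorder())
        for k, rate in enumerate(rates):
            for node in nodes:
                if node.is_leaf:
                    p = self._tip_partial(node.name)
                    s = np.zeros(p.shape[0])
                else:
                    p = None
                    s = None
                    for child in node.children:
                        d = D[(k, id(child))]
                        p = d if p is None else p * d
                        ds = Dscale[(k, id(child))]
                        s = ds if s is None else s + ds
                    m = p.max(axis=1)
                    np.clip(m, _SCALE_FLOOR, None, out=m)
                    p = p / m[:, None]
                    s = s + np.log(m)
                post[(k, id(node))] = p
                scale[(k, id(node))] = s
                if node.parent is not None:
                    t = node.length if node.length is not None else 0.0
                    P = transition_matrix(params, max(t, 0.0), rate, eigen)
                    D[(k, id(node))] = p @ P.T
                    Dscale[(k, id(node))] = s
        return post, scale, D, Dscale

    def loglik(self, tree: PhyloTree, params: GTRGIParams) -> float:
        """Total log-likelihood: sum over patterns of weight x log(mixture)."""
        self._check_tree(tree)
        eigen = params.eigen()
        rates = params.category_rates()
        post, scale, _, _ = self._post_pass(tree, params, eigen, rates)
        pi = np.array(params.base_freqs)
        root = tree.root
        cat_logs = []
        for k in range(len(rates)):
            site = post[(k, id(root))] @ pi
            cat_logs.append(np.log(np.clip(site, _SCALE_FLOOR, None))
                            + scale[(k, id(root))])
        return float(self.weights @ self._mix(np.array(cat_logs), params, pi))

    def _mix(self, cat_logs: np.ndarray, params: GTRGIParams, pi: np.ndarray
             ) -> np.ndarray:
        """Combine per-category pattern log-likelihoods with the invariant
        class into per-pattern site log-likelihoods."""
        w = params.category_weights()
        mix = logsumexp(cat_logs + np.log(w)[:, None], axis=0)
        if params.p_inv > 0:
            inv = self.inv_compat @ pi
            with np.errstate(divide="ignore"):
                inv_log = np.log(params.p_inv * inv)
            mix = np.logaddexp(mix, inv_log)
        return mix

    # -------------------------------------------------- per-edge machinery
    def _out_pass(self, tree, params, eigen, rates, post, scale, D, Dscale):
        """Pre-order 'rest of tree' conditionals.  out[(k, id(v))] is the
        vector at v's parent combining the root prior and every subtree
        except v's; the single-edge likelihood for edge (parent, v) is
        out . (P(t) @ post[v])."""
        pi = np.array(params.base_freqs)
        out, oscale = {}, {}
        for k, rate in enumerate(rates):
            for node in tree.preorder():
                kids = node.children
                if not kids:
                    continue
                if node.parent is None:
                    base = np.broadcast_to(pi, post[(k, id(node))].shape).copy()
                    bscale = np.zeros(base.shape[0])
                else:
                    t = node.length if node.length is not None else 0.0
                    P = transition_matrix(params, max(t, 0.0), rate, eigen)
                    base = out[(k, id(node))] @ P
                    bscale = oscale[(k, id(node))]
                # leave-one-out products of child messages
                n = len(kids)
                prefix = [None] * (n + 1)
                prefix[0] = (np.ones_like(base), np.zeros(base.shape[0]))
                for i, c in enumerate(kids):
                    prefix[i + 1] = (prefix[i][0] * D[(k, id(c))],
                                     prefix[i][1] + Dscale[(k, id(c))])
                suffix = [None] * (n + 1)
                suffix[n] = (np.ones_like(base), np.zeros(base.shape[0]))
                for i in range(n - 1, -1, -1):
                    c = kids[i]
                    suffix[i] = (suffix[i + 1][0] * D[(k, id(c))],
                                 suffix[i + 1][1] + Dscale[(k, id(c))])
                for i, c in enumerate(kids):
                    vec = base * prefix[i][0] * suffix[i + 1][0]
                    sc = bscale + prefix[i][1] + suffix[i + 1][1]
                    m = vec.max(axis=1)
                    np.clip(m, _SCALE_FLOOR, None, out=m)
                    out[(k, id(c))] = vec / m[:, None]
                    oscale[(k, id(c))] = sc + np.log(m)
        return out, oscale

    def _edge_loglik_fn(self, tree, params, node):
        """Returns f(t) = total logL as a function of one branch length,
        with all caches freshly computed (exact, not a surrogate)."""
        eigen = params.eigen()
        rates = params.category_rates()
        post, scale, D, Dscale = self._post_pass(tree, params, eigen, rates)
        out, oscale = self._out_pass(tree, params, eigen, rates,
                                     post, scale, D, Dscale)
        pi = np.array(params.base_freqs)
        pv = [post[(k, id(node))] for k in range(len(rates))]
        ps = [scale[(k, id(node))] for k in range(len(rates))]
        ov = [out[(k, id(node))] for k in range(len(rates))]
        os_ = [oscale[(k, id(node))] for k in range(len(rates))]

        def f(t: float) -> float:
            cat_logs = []
            for k, rate in enumerate(rates):
                P = transition_matrix(params, t, rate, eigen)
                site = np.einsum("pi,pi->p", ov[k], pv[k] @ P.T)
                cat_logs.append(np.log(np.clip(site, _SCALE_FLOOR, None))
                                + ps[k] + os_[k])
            return float(self.weights @ self._mix(np.array(cat_logs), params, pi))

        return f

    def optimize_branch_lengths(self, tree: PhyloTree, params: GTRGIParams,
                                sweeps: int = 2, tol: float = 1e-4) -> float:
        """Coordinate ascent over branch lengths (in place); returns final
        logL.  Monotone: each edge update is accepted only if it improves."""
        self._check_tree(tree)
        current = None
        for _ in range(max(sweeps, 1)):
            improved = False
            for node in tree.postorder():
                if node.parent is None:
                    continue
                f = self._edge_loglik_fn(tree, params, node)
                t0 = node.length if node.length is not None else BRANCH_MIN
                base = f(max(t0, BRANCH_MIN))
                if current is None:
                    current = base
                res = minimize_scalar(lambda t: -f(t), bounds=(BRANCH_MIN, BRANCH_MAX),
                                      method="bounded",
                                      options={"xatol": BRENT_XTOL})
                if -res.fun > base:
                    node.length = float(res.x)
                    if -res.fun > current + tol:
                        improved = True
                    current = -res.fun
                else:
                    node.length = max(t0, BRANCH_MIN)
                    current = max(current, base)
            if not improved:
                break
        return current if current is not None else self.loglik(tree, params)


def log_likelihood(tree: PhyloTree, data, params: GTRGIParams) -> float:
    """Convenience wrapper: pruning log-likelihood of an alignment or
    supermatrix under GTR+G+I."""
    return PruningEngine(data).loglik(tree, params)
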