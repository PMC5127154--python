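"""Nonparametric bootstrap support.

Each replicate resamples the supermatrix's columns (or codon triplets) with
replacement, re-runs the full tree-search pipeline (ML distances ->
neighbor joining -> branch-length smoothing -> NNI) under the model
parameters fitted to the original data, and the support of each internal
edge of the best tree is the percentage of replicate trees containing that
bipartition.  Replicate r draws from seed ``rng_seed + r`` so results are
independent of execution order and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..trees import PhyloTree, majority_rule_consensus  # noqa: F401 (re-export)
from .distances import ml_distance_matrix
from .gtr import GTRGIParams
from .likelihood import PruningEngine
from .nj import neighbor_joining
from .search import SearchSettings, nni_search


@dataclass
class BootstrapConfig:
    n_replicates: int = 1000
    rng_seed: int = 0
    resample_unit: str = "column"  # or "codon"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one bootstrap replicate")
        if self.resample_unit not in ("column", "codon"):
            raise ValueError(f"unknown resample unit {self.resample_unit!r}")


def _replicate_tree(rep: PruningEngine, params: GTRGIParams,
                    settings: SearchSettings) -> PhyloTree:
    taxa, D = ml_distance_matrix(rep, params)
    tree = neighbor_joining(taxa, D)
    tree, _ = nni_search(tree, rep, params, settings)
    return tree


def bootstrap(data, params: GTRGIParams, config: BootstrapConfig,
              best_tree: PhyloTree,
              settings: SearchSettings | None = None
              ) -> tuple[list[PhyloTree], PhyloTree]:
    """Run the bootstrap and annotate ``best_tree``'s internal edges.

    Returns (replicate trees, support-annotated copy of best_tree).
    Model parameters are held fixed at the full-data fit; topology and
    branch lengths are re-estimated per replicate."""
    engine = data if isinstance(data, PruningEngine) else PruningEngine(data)
    settings = settings or SearchSettings(branch_sweeps=1, max_rounds=2)
    trees = []
    for r in range(config.n_replicates):
        rng = np.random.default_rng((config.rng_seed + r) % (2 ** 31))
        rep = engine.resampled(rng, config.resample_unit)
        trees.append(_replicate_tree(rep, params, settings))
    annotated = annotate_support(best_tree, trees)
    return trees, annotated


def annotate_support(tree: PhyloTree, replicate_trees: list[PhyloTree]
                     ) -> PhyloTree:
    """Label each internal edge of ``tree`` with the percentage of replicate
    trees containing the same bipartition."""
    counts: dict[frozenset, int] = {}
    for t in replicate_trees:
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    n = len(replicate_trees)
    out = tree.copy()
    all_leaves = frozenset(out.leaf_names())
    ref = min(all_leaves)
    below: dict[int, frozenset] = {}
    for node in out.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
            continue
        below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is out.root:
            continue
        side = below[id(node)]
        if ref in side:
            side = all_leaves - side
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        node.support = 100.0 * counts.get(side, 0) / n
    return out


def support_values(tree: PhyloTree) -> dict[frozenset, float]:
    """Map each supported bipartition of a tree to its support label."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    below: dict[int, frozenset] = {}
    out: dict[frozenset, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
            continue
        below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is tree.root or node.support is None:
            continue
        side = below[id(node)]
        if ref in side:
            side = all_leaves - side
        out[side] = node.support
    return out
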