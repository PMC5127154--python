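import numpy as np
import pytest
from hypothesis import settings

import mitophylo as mp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SMALL_GENE_LENGTHS = {g: 30 for g in mp.CANONICAL_PCGS}


@pytest.fixture(scope="session")
def small_bundle() -> mp.TruthBundle:
    """Six synthetic mitogenomes with 30-codon genes and known truth."""
    cfg = mp.SimulationConfig(n_taxa=6, branch_scale=0.06, rng_seed=42,
                              gene_lengths=dict(SMALL_GENE_LENGTHS))
    return mp.build_synthetic_genbank(cfg)


@pytest.fixture(scope="session")
def medium_matrix():
    """A 8-taxon, ~1.6 kb codon supermatrix built from generator truth."""
    cfg = mp.SimulationConfig(n_taxa=8, branch_scale=0.06, rng_seed=7,
                              gene_lengths={g: 40 for g in mp.CANONICAL_PCGS})
    tree, genes = mp.simulate.simulate_genes(cfg)
    matrix = mp.concatenate([genes[g].truth_codon for g in mp.CANONICAL_PCGS])
    return tree, matrix


def random_unrooted_tree(names, rng, lo=0.02, hi=0.8):
    """Random unrooted binary tree with uniform branch lengths."""
    nodes = [mp.trees.Node(n, float(rng.uniform(lo, hi))) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = mp.trees.Node(None, float(rng.uniform(lo, hi)))
        parent.add_child(nodes[j])
        parent.add_child(nodes[i])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = mp.trees.Node()
    for n in nodes:
        root.add_child(n)
    return mp.PhyloTree(root, rooted=False)


def path_distances(tree: mp.PhyloTree) -> dict[tuple, float]:
    """Leaf-to-leaf path lengths (the additive metric of the tree)."""
    leaves = tree.leaves()
    dist = {}

    def to_root(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    for i, a in enumerate(leaves):
        pa = to_root(a)
        ia = {id(x): k for k, x in enumerate(pa)}
        for b in leaves[i + 1:]:
            pb = to_root(b)
            d = 0.0
            for k, x in enumerate(pb):
                if id(x) in ia:
                    d = sum(y.length or 0.0 for y in pb[:k])
                    d += sum(y.length or 0.0 for y in pa[:ia[id(x)]])
                    break
            dist[a.name, b.name] = dist[b.name, a.name] = d
    return dist
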