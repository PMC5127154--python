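import numpy as np
import pytest

import mitophylo as mp
from mitophylo.ml.distances import ml_distance
from mitophylo.ml.gtr import GTRGIParams, transition_matrix
from mitophylo.ml.likelihood import PruningEngine
from mitophylo.ml.nj import neighbor_joining

from conftest import path_distances, random_unrooted_tree


def split_lengths(tree):
    """Edge lengths keyed by their (canonical, trivial included) split."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    below, out = {}, {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is None:
            continue
        side = below[id(node)]
        if ref in side:
            side = all_leaves - side
        out[side] = out.get(side, 0.0) + (node.length or 0.0)
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_metric_recovered_exactly(self):
        tree = mp.PhyloTree.from_newick("((A:1,B:2):1,(C:3,D:4):1);")
        names = tree.leaf_names()
        dist = path_distances(tree)
        D = np.array([[dist.get((a, b), 0.0) for b in names] for a in names])
        nj = neighbor_joining(names, D)
        assert nj.rf_distance(tree) == 0
        expected = split_lengths(tree.unrooted())
        got = split_lengths(nj)
        for split, length in expected.items():
            assert got[split] == pytest.approx(length, abs=1e-9)

    def test_three_taxa_three_point_formulas(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        nj = neighbor_joining(["a", "b", "c"], D)
        lens = {n.name: n.length for n in nj.root.children}
        assert lens == {"a": pytest.approx(1.0), "b": pytest.approx(2.0),
                        "c": pytest.approx(3.0)}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        names = [f"t{i}" for i in range(7)]
        tree = random_unrooted_tree(names, rng)
        dist = path_distances(tree)
        perm = list(rng.permutation(names))
        D1 = np.array([[dist.get((a, b), 0.0) for b in names] for a in names])
        D2 = np.array([[dist.get((a, b), 0.0) for b in perm] for a in perm])
        t1 = neighbor_joining(names, D1)
        t2 = neighbor_joining(perm, D2)
        assert t1.topology_hash() == t2.topology_hash()

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(["a", "b", "c"], D)


class TestMLDistance:
    def test_identical_sequences_distance_zero(self):
        engine = PruningEngine({"a": "ACGTACGT" * 10, "b": "ACGTACGT" * 10})
        params = GTRGIParams(n_rate_categories=1)
        assert ml_distance(engine, "a", "b", params) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        rows = {"a": "".join(rng.choice(list("ACGT"), 400)),
                "b": "".join(rng.choice(list("ACGT"), 400))}
        engine = PruningEngine(rows)
        params = GTRGIParams(n_rate_categories=1)
        assert ml_distance(engine, "a", "b", params) == \
            pytest.approx(ml_distance(engine, "b", "a", params))

    def test_zero_shared_columns_rejected(self):
        engine = PruningEngine({"a": "AC--", "b": "--GT"})
        with pytest.raises(ValueError, match="share no"):
            ml_distance(engine, "a", "b", GTRGIParams())

    def test_simulation_consistency_at_known_distance(self):
        # evolve 10,000 sites at true distance 0.3 and re-estimate
        params = GTRGIParams(
            exchangeabilities=(1.5, 6.0, 1.2, 0.9, 8.0, 1.0),
            base_freqs=(0.3, 0.28, 0.14, 0.28),
            gamma_shape=0.5, p_inv=0.0, n_rate_categories=4)
        rng = np.random.default_rng(21)
        d, n = 0.3, 10_000
        pi = np.array(params.base_freqs)
        rates = params.category_rates()
        anc = rng.choice(4, size=n, p=pi)
        site_rates = rates[rng.integers(0, 4, size=n)]
        eigen = params.eigen()
        child = anc.copy()
        for r in np.unique(site_rates):
            idx = site_rates == r
            P = transition_matrix(params, d, float(r), eigen)
            cum = P.cumsum(axis=1)
            u = rng.random(idx.sum())
            child[idx] = (u[:, None] > cum[anc[idx]]).sum(axis=1)
        rows = {"a": "".join("ACGT"[i] for i in anc),
                "b": "".join("ACGT"[i] for i in child)}
        est = ml_distance(PruningEngine(rows), "a", "b", params)
        se = np.sqrt(d / n)  # rough binomial-scale standard error
        assert abs(est - d) < 3 * se + 0.01
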