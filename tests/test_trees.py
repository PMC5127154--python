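import numpy as np
import pytest

import mitophylo as mp
from mitophylo.ml.bootstrap import support_values
from mitophylo.trees import NewickError, majority_rule_consensus

from conftest import random_unrooted_tree


class TestNewick:
    def test_parse_basic(self):
        tree = mp.PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        assert tree.leaf_names() == ["A", "B", "C"]
        internal = [n for n in tree.postorder()
                    if n.children and n.parent is not None]
        assert len(internal) == 1
        assert internal[0].length == 1.0

    def test_support_label_survives_round_trip(self):
        tree = mp.PhyloTree.from_newick("((A:1,B:1)93:1,(C:1,D:1)100:1);")
        text = tree.to_newick()
        assert "93" in text
        again = mp.PhyloTree.from_newick(text)
        internal = [n for n in again.postorder()
                    if n.children and n.parent is not None]
        assert sorted(n.support for n in internal) == [93.0, 100.0]

    def test_unbalanced_parentheses_reports_position(self):
        with pytest.raises(NewickError) as err:
            mp.PhyloTree.from_newick("((A:1,B:1:1,C:2);")
        assert err.value.position >= 0

    def test_quoted_labels(self):
        tree = mp.PhyloTree.from_newick("('Pimelodus pictus':1,'L. alexandri':2,X:1);")
        assert "Pimelodus pictus" in tree.leaf_names()
        assert mp.PhyloTree.from_newick(tree.to_newick()).leaf_names() == \
            tree.leaf_names()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_tree_topology_hash_round_trip(self, seed):
        cfg = mp.SimulationConfig(n_taxa=10, rng_seed=seed)
        tree = mp.simulate_tree(cfg)
        again = mp.PhyloTree.from_newick(tree.to_newick())
        assert again.topology_hash() == tree.topology_hash()

    def test_duplicate_leaf_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            mp.PhyloTree.from_newick("((A:1,A:1):1,C:2);")


class TestRooting:
    def test_outgroup_rooting_and_inverse(self):
        rng = np.random.default_rng(5)
        tree = random_unrooted_tree([f"t{i}" for i in range(8)], rng)
        rooted = tree.root_with_outgroup(["t0"])
        assert rooted.rooted and len(rooted.root.children) == 2
        assert rooted.unrooted().topology_hash() == tree.topology_hash()

    def test_outgroup_must_be_monophyletic(self):
        tree = mp.PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        with pytest.raises(ValueError, match="not monophyletic"):
            tree.root_with_outgroup(["A", "C"])
        with pytest.raises(ValueError, match="not in tree"):
            tree.root_with_outgroup(["Z"])

    def test_split_edge_length_halved(self):
        tree = mp.PhyloTree.from_newick("((A:1,B:2):4,C:1,D:1);")
        rooted = tree.root_with_outgroup(["A", "B"])
        a, b = rooted.root.children
        assert a.length == pytest.approx(2.0)
        assert b.length == pytest.approx(2.0)

    def test_supports_attached_to_bipartitions_survive_rerooting(self):
        rng = np.random.default_rng(11)
        tree = random_unrooted_tree([f"t{i}" for i in range(7)], rng)
        for i, node in enumerate(tree.postorder()):
            if node.children and node.parent is not None:
                node.support = 50.0 + i
        before = support_values(tree)
        rooted = tree.root_with_outgroup(["t3"])
        after = support_values(rooted)
        for split, sup in before.items():
            assert after[split] == sup


class TestMonophyly:
    def test_examples(self):
        tree = mp.PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert tree.is_monophyletic({"A", "B"})[0]
        assert not tree.is_monophyletic({"A", "C"})[0]
        mono, node = tree.is_monophyletic({"C", "D"})
        assert mono and sorted(l.name for l in node.children) == ["C", "D"]


class TestConsensus:
    def test_identical_trees_full_support(self):
        tree = mp.PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        cons = majority_rule_consensus([tree.copy() for _ in range(4)])
        assert cons.bipartitions() == tree.bipartitions()
        sups = [n.support for n in cons.postorder()
                if n.children and n.parent is not None]
        assert all(s == 100.0 for s in sups)

    def test_two_of_three_majority(self):
        t1 = mp.PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = mp.PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t3 = mp.PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        cons = majority_rule_consensus([t1, t2, t3])
        sups = [n.support for n in cons.postorder()
                if n.children and n.parent is not None and n.support]
        assert len(sups) == 1
        assert sups[0] == pytest.approx(200 / 3, abs=0.05)

    def test_consensus_bipartitions_pairwise_compatible(self):
        rng = np.random.default_rng(3)
        names = [f"t{i}" for i in range(8)]
        trees = [random_unrooted_tree(names, rng) for _ in range(7)]
        cons = majority_rule_consensus(trees)
        splits = list(cons.bipartitions())
        for i, s in enumerate(splits):
            for t in splits[i + 1:]:
                # both sides exclude the reference leaf: compatible iff
                # nested or disjoint
                assert s <= t or t <= s or not (s & t)

    def test_differing_leaf_sets_rejected(self):
        t1 = mp.PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        t2 = mp.PhyloTree.from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError, match="leaf sets"):
            majority_rule_consensus([t1, t2])


class TestAgainstDendropy:
    """Independent oracle: dendropy's RF distance on random tree pairs."""

    def test_rf_matches_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(9)
        names = [f"t{i}" for i in range(10)]
        for _ in range(5):
            t1 = random_unrooted_tree(names, rng)
            t2 = random_unrooted_tree(names, rng)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert t1.rf_distance(t2) == expected
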