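import numpy as np
import pytest

import mitophylo as mp
from mitophylo.genes import STOP_CODONS
from mitophylo.simulate import (DEFAULT_GENE_LENGTHS, SimulationConfig,
                                build_synthetic_genbank, simulate_gene,
                                simulate_tree)


class TestSimulateTree:
    def test_three_taxa_shape(self):
        tree = simulate_tree(SimulationConfig(n_taxa=3, rng_seed=1))
        nodes = list(tree.postorder())
        internal = [n for n in nodes if n.children and n.parent is not None]
        branches = [n for n in nodes if n.parent is not None]
        assert len(tree.leaves()) == 3
        assert len(internal) == 1
        assert len(branches) == 4

    def test_deterministic_per_seed(self):
        cfg = SimulationConfig(n_taxa=9, rng_seed=123)
        assert simulate_tree(cfg).to_newick() == simulate_tree(cfg).to_newick()
        other = SimulationConfig(n_taxa=9, rng_seed=124)
        assert simulate_tree(cfg).to_newick() != simulate_tree(other).to_newick()

    def test_height_grows_with_branch_scale(self):
        def mean_tbl(scale):
            total = 0.0
            for seed in range(8):
                cfg = SimulationConfig(n_taxa=8, rng_seed=seed,
                                       branch_scale=scale)
                total += simulate_tree(cfg).total_branch_length()
            return total / 8

        assert mean_tbl(0.2) > mean_tbl(0.02)


class TestSimulateGene:
    def test_zero_branch_lengths_all_identical(self):
        cfg = SimulationConfig(n_taxa=5, rng_seed=4, branch_scale=0.1)
        tree = simulate_tree(cfg)
        for node in tree.postorder():
            if node.parent is not None:
                node.length = 0.0
        sim = simulate_gene(tree, 50, cfg.model, seed=9)
        seqs = set(sim.cds_by_taxon.values())
        assert len(seqs) == 1

    def test_stationary_base_frequencies(self):
        """Empirical base composition of >100k simulated sites matches the
        exact root-codon distribution (stationary frequencies conditioned
        on the codon not being a stop) within 3 binomial SEs."""
        cfg = SimulationConfig(n_taxa=3, rng_seed=2, branch_scale=0.0)
        tree = simulate_tree(cfg)
        model = cfg.model
        sim = simulate_gene(tree, 33_334, model, seed=5)
        seq = next(iter(sim.cds_by_taxon.values()))
        n = len(seq)
        # exact oracle: enumerate the 60 non-stop codons
        pi = dict(zip("ACGT", model.base_freqs))
        expected = {b: 0.0 for b in "ACGT"}
        total_mass = 0.0
        for c1 in "ACGT":
            for c2 in "ACGT":
                for c3 in "ACGT":
                    codon = c1 + c2 + c3
                    if codon in STOP_CODONS:
                        continue
                    mass = pi[c1] * pi[c2] * pi[c3]
                    total_mass += mass
                    for b in codon:
                        expected[b] += mass / 3.0
        for base in "ACGT":
            freq = expected[base] / total_mass
            observed = seq.count(base) / n
            se = np.sqrt(freq * (1 - freq) / n)
            assert abs(observed - freq) < 3 * se

    def test_every_cds_translates_cleanly(self, small_bundle):
        for sim in small_bundle.genes.values():
            for cds in sim.cds_by_taxon.values():
                protein = mp.translate_mito(cds)
                assert len(protein) == len(cds) // 3
                for i in range(0, len(cds), 3):
                    assert cds[i:i + 3] not in STOP_CODONS

    def test_indels_respect_truth_alignment(self):
        cfg = SimulationConfig(n_taxa=6, rng_seed=8, branch_scale=0.08,
                               indel_rate=0.3)
        tree = simulate_tree(cfg)
        sim = simulate_gene(tree, 60, cfg.model, seed=3, indel_rate=0.3)
        lengths = {len(c) for c in sim.cds_by_taxon.values()}
        assert len(lengths) > 1, "indel rate 0.3 should change lengths"
        for taxon, cds in sim.cds_by_taxon.items():
            assert sim.truth_codon.rows[taxon].replace("-", "") == cds
            assert sim.truth_protein.rows[taxon].replace("-", "") == \
                mp.translate_mito(cds)


class TestSyntheticGenbank:
    def test_canonical_gene_order_planted(self, small_bundle):
        for rec in small_bundle.records:
            report = mp.validate_gene_order(rec)
            assert report.counts == (13, 22, 2, 1)
            assert report.deviations == []

    def test_reverse_strand_nd6_recovered(self, small_bundle):
        rec = small_bundle.records[0]
        nd6 = next(f for f in rec.features if f.gene_name == "ND6")
        assert nd6.strand == "-"
        gs = mp.extract_pcgs(rec)
        assert gs.genes["ND6"][0] == \
            small_bundle.genes["ND6"].cds_by_taxon[rec.organism]

    def test_record_length_is_sum_of_features_and_spacers(self, small_bundle):
        rec = small_bundle.records[0]
        feature_total = sum(f.end - f.start + 1 for f in rec.features)
        spacer_total = rec.length_bp - feature_total
        assert 0 <= spacer_total <= 3 * len(rec.features)
        # features are non-overlapping and ordered
        for a, b in zip(rec.features, rec.features[1:]):
            assert a.end < b.start

    def test_bundle_deterministic(self):
        cfg = SimulationConfig(n_taxa=4, rng_seed=77,
                               gene_lengths={g: 20 for g in mp.CANONICAL_PCGS})
        b1 = build_synthetic_genbank(cfg)
        b2 = build_synthetic_genbank(cfg)
        assert b1.tree.to_newick() == b2.tree.to_newick()
        assert [r.sequence for r in b1.records] == [r.sequence for r in b2.records]

    def test_default_gene_lengths_are_realistic_scale(self):
        total = sum(DEFAULT_GENE_LENGTHS.values())
        assert 3 * total == 11_361  # ~11.4 kb of coding sequence
        assert DEFAULT_GENE_LENGTHS["ND5"] == max(DEFAULT_GENE_LENGTHS.values())
        assert DEFAULT_GENE_LENGTHS["ATP8"] == min(DEFAULT_GENE_LENGTHS.values())
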