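import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

import mitophylo as mp
from mitophylo.ml.gtr import GTRGIParams, discrete_gamma_rates, transition_matrix
from mitophylo.ml.likelihood import PruningEngine

from conftest import random_unrooted_tree
from oracles import brute_force_loglik, random_params, random_rows


class TestDiscreteGamma:
    def test_single_category_is_rate_one(self):
        for alpha in (0.1, 1.0, 7.0):
            assert discrete_gamma_rates(alpha, 1).tolist() == [1.0]

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_mean_is_one(self, alpha, k):
        assert discrete_gamma_rates(alpha, k).mean() == pytest.approx(1.0, abs=1e-9)

    def test_matches_quadrature(self):
        alpha, k = 1.0, 4
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1 / alpha)
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mass, _ = quad(lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                           lo, min(hi, 60.0))
            expected.append(mass * k)
        assert np.allclose(discrete_gamma_rates(alpha, k), expected, atol=1e-6)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)


class TestGTRGIParams:
    def test_frequency_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            GTRGIParams(base_freqs=(0.3, 0.3, 0.3, 0.3))

    def test_scaled_rate_mixture_mean_is_one(self):
        p = GTRGIParams(gamma_shape=0.7, p_inv=0.3)
        mixture_mean = (p.category_weights() * p.category_rates()).sum()
        assert mixture_mean == pytest.approx(1.0, abs=1e-9)

    def test_transition_matrix_is_stochastic_and_reversible(self):
        rng = np.random.default_rng(1)
        p = random_params(rng)
        pi = np.array(p.base_freqs)
        for t in (0.01, 0.3, 2.0):
            P = transition_matrix(p, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            flux = pi[:, None] * P
            assert np.allclose(flux, flux.T, atol=1e-12)  # detailed balance

    def test_jukes_cantor_closed_form(self):
        p = GTRGIParams(n_rate_categories=1)
        for d in (0.01, 0.1, 0.5, 1.0, 2.0, 5.0):
            P = transition_matrix(p, d)
            same = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
            diff = 0.25 - 0.25 * np.exp(-4.0 * d / 3.0)
            expected = np.full((4, 4), diff)
            np.fill_diagonal(expected, same)
            assert np.abs(P - expected).max() < 1e-10


class TestPruning:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(6):
            n = int(rng.integers(3, 6))
            names = [f"t{i}" for i in range(n)]
            tree = random_unrooted_tree(names, rng)
            params = random_params(rng)
            rows = random_rows(names, 10, rng)
            ll = PruningEngine(rows).loglik(tree, params)
            assert ll == pytest.approx(brute_force_loglik(tree, rows, params),
                                       abs=1e-9)

    def test_two_taxon_jukes_cantor_closed_form(self):
        params = GTRGIParams(n_rate_categories=1)
        for d in (0.05, 0.3, 1.0):
            tree = mp.PhyloTree.from_newick(f"(a:{d},b:0);")
            ll = PruningEngine({"a": "A", "b": "A"}).loglik(tree, params)
            expected = 0.25 * (0.25 + 0.75 * np.exp(-4 * d / 3))
            assert ll == pytest.approx(np.log(expected), abs=1e-10)

    def test_zero_branch_lengths_identical_columns(self):
        rng = np.random.default_rng(3)
        params = random_params(rng)
        pi = np.array(params.base_freqs)
        tree = mp.PhyloTree.from_newick("((a:0,b:0):0,c:0);")
        rows = {"a": "ACGTA", "b": "ACGTA", "c": "ACGTA"}
        ll = PruningEngine(rows).loglik(tree, params)
        # constant sites at zero distance: full weight on the observed base
        codes = [0, 1, 2, 3, 0]
        assert ll == pytest.approx(sum(np.log(pi[c]) for c in codes), abs=1e-9)

    def test_invariant_to_rerooting(self):
        rng = np.random.default_rng(6)
        names = [f"t{i}" for i in range(7)]
        tree = random_unrooted_tree(names, rng)
        params = random_params(rng)
        rows = random_rows(names, 40, rng)
        engine = PruningEngine(rows)
        base = engine.loglik(tree, params)
        for taxon in names[:3]:
            rerooted = tree.root_with_outgroup([taxon])
            assert engine.loglik(rerooted, params) == pytest.approx(base, abs=1e-8)

    def test_missing_leaf_is_an_error(self):
        tree = mp.PhyloTree.from_newick("((a:1,b:1):1,zz:1);")
        engine = PruningEngine({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        with pytest.raises(ValueError, match="zz"):
            engine.loglik(tree, random_params(np.random.default_rng(0)))

    def test_finite_on_gappy_data(self):
        rng = np.random.default_rng(9)
        names = [f"t{i}" for i in range(5)]
        tree = random_unrooted_tree(names, rng)
        rows = {n: ("-" * 10 if n == "t0" else
                    "".join(rng.choice(list("ACGT"), 10))) for n in names}
        ll = PruningEngine(rows).loglik(tree, random_params(rng))
        assert np.isfinite(ll)
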