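"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the package's pruning machinery: the tree
likelihood is computed by exhaustively summing over every assignment of
states to internal nodes.
"""

import itertools

import numpy as np

from mitophylo.ml.gtr import GTRGIParams, transition_matrix
from mitophylo.ml.likelihood import CODE
from mitophylo.trees import PhyloTree


def brute_force_loglik(tree: PhyloTree, rows: dict[str, str],
                       params: GTRGIParams) -> float:
    nodes = list(tree.postorder())
    internals = [n for n in nodes if n.children]
    leaves = [n for n in nodes if not n.children]
    eigen = params.eigen()
    rates = params.category_rates()
    weights = params.category_weights()
    pi = np.array(params.base_freqs)
    L = len(next(iter(rows.values())))
    total = 0.0
    for site in range(L):
        obs = {n.name: rows[n.name][site] for n in leaves}
        site_lik = 0.0
        for k, r in enumerate(rates):
            Ps = {id(n): transition_matrix(params, n.length or 0.0, r, eigen)
                  for n in nodes if n.parent is not None}
            lik = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                states = {id(n): a for n, a in zip(internals, assign)}
                p = pi[states[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    parent_state = states[id(n.parent)]
                    if n.children:
                        p *= Ps[id(n)][parent_state, states[id(n)]]
                    elif obs[n.name] in CODE:
                        p *= Ps[id(n)][parent_state, CODE[obs[n.name]]]
                    # missing data: sum over leaf states equals 1
                lik += p
            site_lik += weights[k] * lik
        if params.p_inv > 0:
            seen = {CODE[obs[n.name]] for n in leaves if obs[n.name] in CODE}
            if len(seen) == 0:
                inv = 1.0
            elif len(seen) == 1:
                inv = pi[seen.pop()]
            else:
                inv = 0.0
            site_lik += params.p_inv * inv
        total += np.log(site_lik)
    return total


def random_params(rng: np.random.Generator, k: int = 3) -> GTRGIParams:
    return GTRGIParams(
        exchangeabilities=tuple(rng.uniform(0.3, 3.0, 6)),
        base_freqs=tuple(rng.dirichlet([5.0] * 4)),
        gamma_shape=float(rng.uniform(0.3, 2.0)),
        p_inv=float(rng.uniform(0.0, 0.4)),
        n_rate_categories=k,
    )


def random_rows(names, n_sites, rng: np.random.Generator) -> dict[str, str]:
    letters = list("ACGT-N")
    probs = [0.22, 0.22, 0.22, 0.22, 0.06, 0.06]
    return {n: "".join(rng.choice(letters, size=n_sites, p=probs))
            for n in names}
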