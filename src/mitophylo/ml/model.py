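"""Model/Results facade over the ML machinery.

``PhyloGTRModel`` is constructed from a codon supermatrix (or any aligned
nucleotide rows); ``fit()`` runs the full inference — empirical starting
frequencies, ML pairwise distances, neighbor joining, alternating
branch-length/model optimization, NNI search — and returns a
``PhyloMLResults`` carrying the tree, the fitted GTR+G+I parameters, the
log-likelihood and a ``summary()`` table.  Bootstrapping, outgroup rooting
and clade (monophyly) tests hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..trees import PhyloTree
from .bootstrap import BootstrapConfig, annotate_support, bootstrap, support_values
from .distances import ml_distance_matrix
from .gtr import GTRGIParams, empirical_base_freqs
from .likelihood import PruningEngine
from .nj import neighbor_joining
from .search import SearchSettings, nni_search, optimize


class PhyloGTRModel:
    """Maximum-likelihood phylogeny under GTR+G+I for one alignment."""

    def __init__(self, data, n_rate_categories: int = 4):
        self.engine = data if isinstance(data, PruningEngine) else PruningEngine(data)
        self.n_rate_categories = n_rate_categories
        self.supermatrix = data if hasattr(data, "partitions") else None

    @classmethod
    def from_alignment(cls, rows: dict[str, str], **kwargs) -> "PhyloGTRModel":
        return cls(PruningEngine(rows), **kwargs)

    @property
    def taxa(self) -> list[str]:
        return list(self.engine.taxa)

    def start_params(self) -> GTRGIParams:
        freqs = empirical_base_freqs(
            {t: "".join("ACGT"[c] for c in self.engine.patterns[i] if c < 4)
             for i, t in enumerate(self.engine.taxa)})
        return GTRGIParams(base_freqs=freqs, gamma_shape=1.0, p_inv=0.02,
                           n_rate_categories=self.n_rate_categories)

    def start_tree(self, params: Optional[GTRGIParams] = None) -> PhyloTree:
        params = params or self.start_params()
        taxa, D = ml_distance_matrix(self.engine, params)
        return neighbor_joining(taxa, D)

    def loglike(self, tree: PhyloTree, params: GTRGIParams) -> float:
        return self.engine.loglik(tree, params)

    def fit(self, start_params: Optional[GTRGIParams] = None,
            settings: Optional[SearchSettings] = None,
            search_topology: bool = True) -> "PhyloMLResults":
        settings = settings or SearchSettings()
        params = start_params or self.start_params()
        tree = self.start_tree(params)
        tree, params, loglik = optimize(tree, self.engine, params, settings)
        if search_topology and len(self.taxa) > 3:
            tree, loglik = nni_search(tree, self.engine, params, settings)
            tree, params, loglik = optimize(tree, self.engine, params, settings)
        return PhyloMLResults(model=self, tree=tree, params=params,
                              loglik=loglik, settings=settings)


@dataclass
class PhyloMLResults:
    """Fitted ML phylogeny: tree, model parameters, diagnostics."""

    model: PhyloGTRModel
    tree: PhyloTree
    params: GTRGIParams
    loglik: float
    settings: SearchSettings = field(default_factory=SearchSettings)
    bootstrap_trees: list = field(default_factory=list)

    # ------------------------------------------------------------- analysis
    def bootstrap(self, n_replicates: int = 1000, seed: int = 0,
                  resample_unit: str = "column") -> "PhyloMLResults":
        """Nonparametric bootstrap; returns a results object whose tree
        carries percentage supports on internal edges."""
        config = BootstrapConfig(n_replicates=n_replicates, rng_seed=seed,
                                 resample_unit=resample_unit)
        trees, annotated = bootstrap(self.model.engine, self.params, config,
                                     self.tree)
        return PhyloMLResults(model=self.model, tree=annotated,
                              params=self.params, loglik=self.loglik,
                              settings=self.settings, bootstrap_trees=trees)

    def root_with_outgroup(self, outgroup) -> "PhyloMLResults":
        rooted = self.tree.root_with_outgroup(outgroup)
        return PhyloMLResults(model=self.model, tree=rooted,
                              params=self.params, loglik=self.loglik,
                              settings=self.settings,
                              bootstrap_trees=self.bootstrap_trees)

    def test_clade(self, taxa) -> dict:
        """Monophyly test: is ``taxa`` an exact clade of the (rooted) tree,
        and with what bootstrap support?"""
        mono, node = self.tree.is_monophyletic(taxa)
        support = node.support if (mono and node is not None) else None
        return {"taxa": sorted(taxa), "monophyletic": mono, "support": support}

    def supports(self) -> dict[frozenset, float]:
        return support_values(self.tree)

    # -------------------------------------------------------------- summary
    def summary(self) -> str:
        p = self.params
        ex_names = ("AC", "AG", "AT", "CG", "CT", "GT")
        lines = [
            "Maximum-likelihood phylogeny (GTR+G+I)",
            "=" * 46,
            f"Taxa:                {len(self.model.taxa)}",
            f"Alignment columns:   {self.model.engine.n_sites}",
            f"Distinct patterns:   {self.model.engine.patterns.shape[1]}",
            f"Log-likelihood:      {self.loglik:.4f}",
            f"Tree length:         {self.tree.total_branch_length():.4f}",
            "-" * 46,
            "Exchangeabilities (GT = 1):",
        ]
        for name, val in zip(ex_names, p.normalized().exchangeabilities):
            lines.append(f"    {name}: {val:8.4f}")
        lines.append("Base frequencies:")
        for base, val in zip("ACGT", p.base_freqs):
            lines.append(f"    {base}: {val:8.4f}")
        lines += [
            f"Gamma shape (alpha): {p.gamma_shape:.4f} "
            f"({p.n_rate_categories} categories)",
            f"Invariant fraction:  {p.p_inv:.4f}",
        ]
        if self.bootstrap_trees:
            lines.append(f"Bootstrap replicates: {len(self.bootstrap_trees)}")
        return "\n".join(lines)

    def params_report(self) -> str:
        """Plain-text key=value dump of the fitted model."""
        p = self.params.normalized()
        ex_names = ("AC", "AG", "AT", "CG", "CT", "GT")
        out = [f"loglik={self.loglik:.6f}"]
        out += [f"rate_{n}={v:.6f}" for n, v in zip(ex_names, p.exchangeabilities)]
        out += [f"freq_{b}={v:.6f}" for b, v in zip("ACGT", p.base_freqs)]
        out += [f"gamma_shape={p.gamma_shape:.6f}",
                f"p_inv={p.p_inv:.6f}",
                f"n_rate_categories={p.n_rate_categories}"]
        return "\n".join(out)
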