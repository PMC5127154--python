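"""Ground-truthed synthetic data for every pipeline stage.

Generates random rooted trees (Yule), simulates the 13 mitochondrial
protein-coding genes along them under GTR+G(+I) at the nucleotide level
(with optional protein-level indels producing a known true alignment), and
packages each taxon as a GenBank-style circular mitogenome with the
canonical teleost gene arrangement (13 PCGs, 22 tRNAs, 2 rRNAs, control
region; ND6 and eight tRNAs on the minus strand).

Stop codons (TAA/TAG/AGA/AGG under the vertebrate mitochondrial code) are
excluded at the root and re-drawn whenever a substitution creates one, so
every simulated CDS translates cleanly; a terminal TAA is appended when the
genes are placed on the genome.  All randomness flows from one seed:
identical configs produce identical bundles.

Default gene lengths approximate real teleost mitochondrial PCGs
(ATP8 ~ 55 codons up to ND5 ~ 600), totalling 3,787 codons (11,361 nt of
supermatrix when no indels are simulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genes import CANONICAL_PCGS, CANONICAL_TELEOST_ORDER, STOP_CODONS
from .ml.gtr import BASES, GTRGIParams, transition_matrix
from .msa import ProteinAlignment
from .seq_formats import GeneFeature, MitoRecord
from .supermatrix import CodonAlignment
from .trees import Node, PhyloTree

#: codon counts close to the real teleost mitochondrial gene lengths
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ND1": 324, "ND2": 348, "COX1": 516, "COX2": 230, "ATP8": 55,
    "ATP6": 227, "COX3": 261, "ND3": 116, "ND4L": 98, "ND4": 460,
    "ND5": 600, "ND6": 172, "CYTB": 380,
}

#: a moderately asymmetric, AT-rich model in the range reported for fish
#: mitogenomes: transitions (AG, CT) well above transversions, alpha 0.5,
#: one fifth of sites invariant
DEFAULT_MODEL = GTRGIParams(
    exchangeabilities=(1.5, 6.0, 1.2, 0.9, 8.0, 1.0),
    base_freqs=(0.30, 0.28, 0.14, 0.28),
    gamma_shape=0.5,
    p_inv=0.2,
    n_rate_categories=4,
)

_PLACEHOLDER_LENGTHS = {"tRNA": 70, "rrnS": 950, "rrnL": 1650, "D-loop": 880}


@dataclass
class SimulationConfig:
    n_taxa: int = 12
    tree_shape: str = "yule"  # or "fixed_newick"
    fixed_newick: str | None = None
    branch_scale: float = 0.05
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    model: GTRGIParams = DEFAULT_MODEL
    rng_seed: int = 0
    indel_rate: float = 0.0  # protein-level events per codon per unit length

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        for gene, n in self.gene_lengths.items():
            if n < 2:
                raise ValueError(f"{gene}: gene length must be >= 2 codons")
        if self.tree_shape not in ("yule", "fixed_newick"):
            raise ValueError(f"unknown tree shape {self.tree_shape!r}")
        if self.tree_shape == "fixed_newick" and not self.fixed_newick:
            raise ValueError("fixed_newick shape requires a newick string")


def taxon_name(i: int) -> str:
    return f"taxon{i + 1:02d}"


# -------------------------------------------------------------------- trees
def simulate_tree(config: SimulationConfig) -> PhyloTree:
    """Rooted Yule topology with i.i.d. exponential branch lengths of mean
    ``branch_scale`` (or the supplied fixed newick)."""
    if config.tree_shape == "fixed_newick":
        return PhyloTree.from_newick(config.fixed_newick)
    rng = np.random.default_rng(config.rng_seed)
    root = Node()
    lineages = [root.add_child(Node()), root.add_child(Node())]
    while len(lineages) < config.n_taxa:
        k = int(rng.integers(len(lineages)))
        split = lineages.pop(k)
        lineages.insert(k, split.add_child(Node()))
        lineages.insert(k + 1, split.add_child(Node()))
    for i, leaf in enumerate(lineages):
        leaf.name = taxon_name(i)
    for node in PhyloTree(root).postorder():
        if node.parent is not None:
            node.length = float(rng.exponential(config.branch_scale))
    return PhyloTree(root, rooted=True)


# -------------------------------------------------------------------- genes
@dataclass
class GeneSimulation:
    """One simulated gene: per-taxon CDS plus the true alignments."""

    gene_name: str
    cds_by_taxon: dict[str, str]          # stop-trimmed coding sequences
    truth_protein: ProteinAlignment
    truth_codon: CodonAlignment


_STOPS = sorted(STOP_CODONS)


def _draw_codons(n: int, pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) stationary codons with stops re-drawn."""
    codons = rng.choice(4, size=(n, 3), p=pi)
    while True:
        bad = _stop_mask(codons)
        if not bad.any():
            return codons
        codons[bad] = rng.choice(4, size=(int(bad.sum()), 3), p=pi)


def _stop_mask(codons: np.ndarray) -> np.ndarray:
    strings = np.array(["".join(BASES[b] for b in row) for row in codons])
    return np.isin(strings, _STOPS)


def _evolve(states: np.ndarray, rates: np.ndarray, t: float,
            params: GTRGIParams, eigen, rng: np.random.Generator) -> np.ndarray:
    """One branch of nucleotide evolution; sites with rate 0 are invariant.
    ``states``/``rates`` have shape (n_codons, 3).  Stop codons created by
    substitution are re-drawn from the parent codon."""
    flat = states.ravel()
    rflat = rates.ravel()
    child = flat.copy()
    for rate in np.unique(rflat):
        if rate == 0.0:
            continue
        idx = np.nonzero(rflat == rate)[0]
        P = transition_matrix(params, t, float(rate), eigen)
        cum = P.cumsum(axis=1)
        u = rng.random(idx.size)
        child[idx] = (u[:, None] > cum[flat[idx]]).sum(axis=1)
    out = child.reshape(states.shape)
    for _ in range(1000):
        bad = np.nonzero(_stop_mask(out))[0]
        if bad.size == 0:
            return out
        for ci in bad:
            for s in range(3):
                rate = rates[ci, s]
                if rate == 0.0:
                    out[ci, s] = states[ci, s]
                    continue
                P = transition_matrix(params, t, float(rate), eigen)
                out[ci, s] = int(rng.choice(4, p=P[states[ci, s]]))
    raise RuntimeError("could not escape stop codons")  # pragma: no cover


def _draw_rates(n_codons: int, params: GTRGIParams,
                rng: np.random.Generator) -> np.ndarray:
    """Per-site rates: 0 with probability p_inv, else a scaled discrete-gamma
    category rate (the same convention the likelihood uses)."""
    cat = params.category_rates()
    rates = cat[rng.integers(0, len(cat), size=(n_codons, 3))]
    rates[rng.random((n_codons, 3)) < params.p_inv] = 0.0
    return rates


def simulate_gene(tree: PhyloTree, length_codons: int, model: GTRGIParams,
                  seed: int | np.random.Generator = 0,
                  gene_name: str = "gene", indel_rate: float = 0.0
                  ) -> GeneSimulation:
    """Simulate one protein-coding gene along a tree.

    Substitutions follow GTR+G+I; optional protein-level indel events
    (Poisson per branch, geometric codon lengths, insertions and deletions
    equally likely) yield the true alignment alongside the sequences."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pi = np.array(model.base_freqs)
    eigen = model.eigen()

    next_col = [length_codons]
    master: list[int] = list(range(length_codons))

    root_states = _draw_codons(length_codons, pi, rng)
    root_rates = _draw_rates(length_codons, model, rng)

    leaf_data: dict[str, tuple[list[int], np.ndarray]] = {}

    def recurse(node: Node, cols: list[int], states: np.ndarray,
                rates: np.ndarray) -> None:
        if node.is_leaf:
            leaf_data[node.name] = (cols, states)
            return
        for child in node.children:
            t = child.length or 0.0
            c_states = _evolve(states, rates, t, model, eigen, rng) \
                if t > 0 else states.copy()
            c_cols, c_rates = list(cols), rates.copy()
            if indel_rate > 0 and t > 0:
                c_cols, c_states, c_rates = _apply_indels(
                    c_cols, c_states, c_rates, t, indel_rate, model, master,
                    next_col, pi, rng)
            recurse(child, c_cols, c_states, c_rates)

    recurse(tree.root, master[:], root_states, root_rates)

    present = {c for cols, _ in leaf_data.values() for c in cols}
    order = [c for c in master if c in present]
    col_pos = {c: i for i, c in enumerate(order)}

    from .genes import translate_mito  # local import avoids a cycle at load

    cds, prot_rows, codon_rows = {}, {}, {}
    for taxon, (cols, states) in leaf_data.items():
        codon_strs = ["".join(BASES[b] for b in row) for row in states]
        cds[taxon] = "".join(codon_strs)
        prot = list(translate_mito(cds[taxon])) if cds[taxon] else []
        prow = ["-"] * len(order)
        crow = ["---"] * len(order)
        for c, aa, codon in zip(cols, prot, codon_strs):
            prow[col_pos[c]] = aa
            crow[col_pos[c]] = codon
        prot_rows[taxon] = "".join(prow)
        codon_rows[taxon] = "".join(crow)

    return GeneSimulation(
        gene_name=gene_name,
        cds_by_taxon=cds,
        truth_protein=ProteinAlignment(gene_name, prot_rows),
        truth_codon=CodonAlignment(gene_name, codon_rows),
    )


def _apply_indels(cols, states, rates, t, indel_rate, model, master,
                  next_col, pi, rng):
    n_events = rng.poisson(indel_rate * t * max(len(cols), 1))
    for _ in range(n_events):
        if len(cols) < 3:
            break
        length = min(int(rng.geometric(0.5)), max(len(cols) // 4, 1))
        if rng.random() < 0.5:  # deletion
            pos = int(rng.integers(0, len(cols) - length + 1))
            del cols[pos:pos + length]
            states = np.delete(states, slice(pos, pos + length), axis=0)
            rates = np.delete(rates, slice(pos, pos + length), axis=0)
        else:  # insertion after position pos-1
            pos = int(rng.integers(0, len(cols) + 1))
            new_ids = list(range(next_col[0], next_col[0] + length))
            next_col[0] += length
            anchor = master.index(cols[pos - 1]) + 1 if pos > 0 else 0
            master[anchor:anchor] = new_ids
            cols[pos:pos] = new_ids
            new_states = _draw_codons(length, pi, rng)
            new_rates = _draw_rates(length, model, rng)
            states = np.insert(states, pos, new_states, axis=0)
            rates = np.insert(rates, pos, new_rates, axis=0)
    return cols, states, rates


# ------------------------------------------------------------------ genomes
@dataclass
class TruthBundle:
    """Everything the generator knows: the tree, per-gene truth, records."""

    config: SimulationConfig
    tree: PhyloTree
    genes: dict[str, GeneSimulation]
    records: list[MitoRecord]


def simulate_genes(config: SimulationConfig, tree: PhyloTree | None = None
                   ) -> tuple[PhyloTree, dict[str, GeneSimulation]]:
    tree = tree or simulate_tree(config)
    seeds = np.random.SeedSequence(config.rng_seed).spawn(len(config.gene_lengths))
    genes = {}
    for seq, (gene, n_codons) in zip(seeds, config.gene_lengths.items()):
        genes[gene] = simulate_gene(
            tree, n_codons, config.model, np.random.default_rng(seq),
            gene_name=gene, indel_rate=config.indel_rate)
    return tree, genes


def build_synthetic_genbank(config: SimulationConfig) -> TruthBundle:
    """Per taxon, one circular GenBank-like record: the simulated CDS placed
    in canonical teleost order (terminal TAA appended; ND6 on the minus
    strand), placeholder tRNA/rRNA/control-region features, and 0-3 random
    spacer nucleotides between features."""
    tree, genes = simulate_genes(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 987654321]))
    records = []
    for leaf in tree.leaf_names():
        seq_parts: list[str] = []
        features: list[GeneFeature] = []
        pos = 1
        for name, kind, strand in CANONICAL_TELEOST_ORDER:
            if kind == "CDS":
                segment = genes[name].cds_by_taxon[leaf] + "TAA"
                if strand == "-":
                    segment = _revcomp(segment)
            else:
                key = name if name in ("rrnS", "rrnL") else \
                    ("D-loop" if kind == "D-loop" else "tRNA")
                length = _PLACEHOLDER_LENGTHS[key]
                segment = "".join(BASES[b] for b in rng.choice(4, size=length))
            end = pos + len(segment) - 1
            features.append(GeneFeature(
                gene_name=name, feature_kind=kind, start=pos, end=end,
                strand=strand, transl_table=2, codon_start=1))
            seq_parts.append(segment)
            pos = end + 1
            spacer = int(rng.integers(0, 4))
            if spacer:
                seq_parts.append("".join(BASES[b] for b in rng.choice(4, size=spacer)))
                pos += spacer
        records.append(MitoRecord(
            accession=f"SYN{tree.leaf_names().index(leaf) + 1:03d}",
            organism=leaf,
            sequence="".join(seq_parts),
            features=features,
            is_circular=True,
        ))
    return TruthBundle(config=config, tree=tree, genes=genes, records=records)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
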