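# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `mitophylo`, in the spirit of a methods appendix.

## Gene extraction and translation

Mitogenome records are parsed from GenBank flat files (Biopython underneath)
into a `MitoRecord` with 1-based inclusive coordinates; features joined
across the circular origin are flagged `wraps_origin`.  Gene symbols are
resolved through an editable synonym table
(`src/mitophylo/data/gene_synonyms.tsv`): matching is case-insensitive and
ignores spaces, dashes, underscores and periods, so `COI`, `MT-CO1` and
`cox 1` all resolve to `COX1`.  Unknown labels resolve to `None` rather than
raising — annotation noise is reported, not fatal.

Translation uses NCBI code table 2 (vertebrate mitochondrial): ATA → Met,
TGA → Trp, AGA/AGG → stop.  Reading frames honor the `codon_start`
qualifier.  A single terminal stop codon is trimmed, and a trailing
incomplete codon of 1–2 nt is treated as a polyadenylation-completed stop
and dropped — standard practice for mitochondrial annotations, where CDS
frequently end in `T` or `TA`.  An internal stop codon is always an error
(it indicates a frame or annotation problem).  Codons containing N
translate to X.  Consequently every stored CDS is exactly three times its
protein length, and stop codons never enter the supermatrix.

Gene order validation rotates the observed feature list so tRNA-Phe comes
first (the genome is circular) and compares name/kind/strand position by
position against the canonical teleost arrangement
(`data/teleost_gene_order.tsv`); every mismatch yields one human-readable
deviation line, and counts of PCG/tRNA/rRNA/control-region features are
reported regardless.

## Protein alignment

Per-gene alignments are computed at the protein level.  Pairwise global
alignment is affine-gap Needleman–Wunsch (three-state DP) under BLOSUM62
with gap open −10 and extend −1 (a gap of length *g* costs −10 − *g*); ties
prefer substitution over a gap in the first sequence over a gap in the
second, making results deterministic.  The DP is vectorized row-wise; the
within-row horizontal-gap recursion is solved with a running maximum over
gap-opening candidates, which is exact for affine penalties.

Multiple alignment is progressive: 3-mer set distances feed a UPGMA guide
tree (scipy's average-linkage), profiles are merged leaf-to-root with
profile–profile NW using mean-of-pairs column scores (gap positions
contribute zero), and existing gaps are frozen ("once a gap, always a
gap").  All-gap columns produced by merging are dropped.  Mitochondrial
proteins are short and conserved, so this simple strategy aligns them
essentially unambiguously; BLOSUM62 and the gap costs are configuration
knobs, and the pipeline accepts externally pre-aligned per-gene FASTA
(`aligned_dir`) for users who prefer MAFFT or similar.  Note that the
choice of aligner changes the supermatrix length when indels are present,
so published column counts are reproducible exactly only with the original
alignments.

## Back-translation and concatenation

Each aligned residue is replaced by its source codon in reading order, gaps
become `---`, and X residues emit their original (N-containing) codon; the
CDS must translate to exactly the gap-stripped row, checked per taxon with
the first discordant residue reported.  Gene blocks are concatenated in
canonical genome order (ND1 … CYTB — the order is arbitrary for ML, fixed
for determinism); a taxon missing a gene receives an all-gap block there
and is flagged in the occupancy report.  Every partition length is
divisible by three and the partition map tiles the matrix exactly — both
are enforced invariants.

## Substitution model

GTR+G+I.  The rate matrix is `Q_ij = s_ij π_j` with six exchangeabilities
(order AC, AG, AT, CG, CT, GT; GT pinned to 1) and stationary frequencies
π, normalized so `−Σ π_i Q_ii = 1`: branch lengths are expected
substitutions per site.  `P(t) = exp(Qt)` is computed through the
symmetrized eigendecomposition (`diag(√π) Q diag(1/√π)` is symmetric for a
reversible Q), with tiny negative entries clipped and rows renormalized.

Among-site rate variation: a proportion `p_inv` of sites is invariant
(rate 0); the remaining sites draw from `k = 4` equal-probability
discrete-gamma categories with mean-of-bin rates (the conditional bin mean
has a closed form through the shape-(α+1) CDF, and preserves the unit mean
exactly, unlike the median-of-bin variant).  The gamma rates are divided by
`(1 − p_inv)` so the full mixture has mean rate exactly 1 — without this,
branch lengths would silently rescale with `p_inv` and parameter recovery
would be ill-defined.  The synthetic-data generator uses the identical
convention.

## Likelihood computation

Felsenstein pruning over unique site patterns with multiplicity weights;
gaps, N and `?` are missing data (all-ones partial likelihood), not a fifth
state.  Per-node rescaling (divide by the per-pattern maximum, accumulate
logs) keeps partial likelihoods finite at any scale.  The invariant-class
contribution of a pattern is `Σ_x π_x` over states x consistent with every
non-missing observation (so 0 for variable patterns, `π_x` for constant
ones, 1 for all-missing), mixed with the gamma categories in log space.

Branch lengths are optimized one edge at a time by bounded Brent search in
[1e−8, 10] with tolerance 1e−6.  With the subtree (post-order) and
rest-of-tree (pre-order) conditionals cached, the log-likelihood as a
function of one branch length costs O(patterns × states) per evaluation;
caches are refreshed before each edge, so every accepted update is an exact
coordinate-ascent step and the log-likelihood is monotone by construction.

Model fitting alternates branch-length sweeps with quasi-Newton (L-BFGS-B,
numeric gradients) optimization of the model parameters on unconstrained
transforms: log exchangeabilities, softmax frequencies, log α (clamped to
[0.02, 100]), logit p_inv.  A proposal is accepted only if it improves the
likelihood; rounds stop when the gain falls below 1e−4 or after 20 rounds.

## Tree search

The starting tree is neighbor joining (canonical Saitou–Nei; taxa sorted
before the algorithm runs so the result is permutation-invariant, remaining
ties broken lexicographically; negative branch estimates clamped to zero
with the deficit moved to the sibling) on pairwise ML distances — each pair
maximized one-dimensionally under the current model from the weighted 4×4
joint base counts, capped at 5 substitutions/site.

Topology search is NNI hill-climbing: both rearrangements of every internal
edge are scored cheaply by re-optimizing only the central (swapped) branch
against fresh conditionals; the best strictly-improving move is applied and
branch lengths re-smoothed.  When no candidate improves on the quick score,
the top three are re-scored with a local pass over all edges adjacent to
the swap before the search concedes a local optimum — the cheap score
underestimates some beneficial swaps, and this refinement escapes those
shallow traps at negligible cost in the common case.  The search is
deterministic given the input tree and postorder edge enumeration.

## Bootstrap

Nonparametric bootstrap over alignment columns (or codon triplets —
resampling unit is a config switch).  Resampling is implemented as
re-weighting of the compressed site patterns, so replicates reuse the
pattern matrix.  Each replicate re-runs ML distances → NJ → branch-length
smoothing → NNI under the model parameters fitted to the original data;
re-estimating the substitution model per replicate would multiply the cost
several-fold for little effect on supports and is standard practice in fast
bootstrap implementations.  Replicate *r* draws from seed
`base_seed + r`, making results independent of execution order and
bit-reproducible.  Support of an internal edge of the best tree is the
percentage of replicate trees containing that bipartition; supports are
attached to bipartitions, not node identities, and therefore survive
re-rooting.  A 50%-majority-rule consensus tree is also available.

## Rooting and clade tests

Outgroup rooting requires the outgroup to form one side of a bipartition of
the unrooted tree (otherwise an error names the offending taxa) and splits
that edge's length equally.  A clade test asks whether a taxon set is
exactly the descendant leaf set of some node of the rooted tree, and
reports the bootstrap support of the corresponding edge.

## Synthetic data

The generator emulates a mitogenome study: a Yule topology with i.i.d.
exponential branch lengths (mean `branch_scale`, default 0.05
substitutions/site — enough divergence for informative variation without
saturation), 13 genes at realistic teleost lengths (ATP8 ≈ 55 codons to
ND5 ≈ 600; 3,787 codons ≈ 11.4 kb total), evolved under GTR+G+I with
mildly AT-rich frequencies, transition/transversion asymmetry, α = 0.5 and
p_inv = 0.2 — values in the range typically estimated from fish
mitogenomes.  Root codons are drawn from the stationary distribution
conditioned on not being a stop, and substitutions that create a stop are
re-drawn, so every simulated CDS translates cleanly; this conditioning
biases base composition slightly (~1.6% for A) relative to the raw
stationary frequencies, and tests compare against the exact conditioned
distribution.  Optional protein-level indels (Poisson events per branch,
geometric codon-block lengths, insertions and deletions equally likely)
produce a known true alignment alongside the sequences.  Each taxon is
packaged as a circular GenBank record in canonical teleost gene order with
placeholder tRNA/rRNA/control-region features and 0–3 random spacer
nucleotides between features.

What the simulator does *not* emulate: compositional heterogeneity across
lineages, codon-level selection (dN/dS), realistic RNA-gene sequences,
rate autocorrelation along the sequence, or annotation errors.  Passing
tests therefore demonstrate correctness of the algorithms under the
generating model, not robustness to every artifact of real mitogenome
data.

## Problem sizes and defaults

The test suite exercises the full pipeline at 6–12 taxa and 1.5–15 kb; the
end-to-end recovery check uses 12 taxa × 15,000 sites with 100 bootstrap
replicates, and the acceptance script runs the default 12-taxon,
11,361-column study bundle with a 100-replicate bootstrap — sizes chosen so
the complete analysis finishes in minutes on a single core while leaving
the statistical checks (parameter recovery within 25%, true-edge supports
≥ 90) well-powered.  All stochastic steps flow from one user-supplied seed.

## Known limitations

- Single concatenated GTR+G+I model; no per-partition models, no model
  selection (the model family is fixed), no Bayesian inference, no SPR/TBR.
- NNI hill-climbing can in principle stop at a local optimum; for the tens
  of taxa this package targets, NJ starting trees leave little for NNI to
  fix, but pathological data may require restarting from other topologies.
- The in-repo aligner is deliberately simple (no iterative refinement or
  consistency objectives); supply external alignments for
  publication-grade column counts.
- Likelihoods are reported up to the usual arbitrary constant conventions;
  absolute values are comparable only within one alignment.
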