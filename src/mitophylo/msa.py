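"""Protein multiple sequence alignment.

Per-gene protein alignments are built in-repo: pairwise global
Needleman-Wunsch with affine gaps (three-state DP), and progressive
alignment over a k-mer/UPGMA guide tree with profile-profile merging
("once a gap, always a gap").  Mitochondrial proteins are short and highly
conserved, so a general-purpose matrix (BLOSUM62 by default) suffices; the
matrix and gap penalties are configuration knobs.

A gap of length g costs ``gap_open + g * gap_extend`` (defaults -10, -1).
Ties are broken deterministically: substitution preferred over a gap in the
first sequence, preferred over a gap in the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

NEG = -1e30  # effectively -inf for the DP


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    arr = np.array(mat, dtype=float)
    index = {c: i for i, c in enumerate(alphabet)}
    return arr, index


@dataclass
class AlignParams:
    """Scoring configuration for protein alignment."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def matrix(self):
        return _load_matrix(self.matrix_name)


@dataclass
class ProteinAlignment:
    """A per-gene protein MSA; rows are aligned strings over residues + '-'."""

    gene_name: str
    rows: dict[str, str]
    n_cols: int = field(default=0)

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_name}: unequal row lengths {sorted(lengths)}")
        self.n_cols = lengths.pop()
        if self.n_cols == 0:
            raise ValueError(f"{self.gene_name}: empty alignment")
        cols_all_gap = [
            i for i in range(self.n_cols)
            if all(r[i] == "-" for r in self.rows.values())
        ]
        if cols_all_gap:
            raise ValueError(f"{self.gene_name}: all-gap columns {cols_all_gap[:5]}")

    def stripped(self, taxon: str) -> str:
        return self.rows[taxon].replace("-", "")


def _encode(seq: str, index: dict[str, int], what: str) -> np.ndarray:
    try:
        return np.array([index[c] for c in seq], dtype=np.int32)
    except KeyError as exc:
        raise ValueError(f"{what}: residue {exc.args[0]!r} not in substitution "
                         "matrix alphabet") from exc


def _nw_core(S: np.ndarray, go: float, ge: float):
    """Affine-gap global DP on a precomputed column-score matrix.

    S has shape (n, m): score of pairing row-unit i with column-unit j.
    Returns (score, ops) with ops a start-to-end list over {'M','GA','GB'};
    'GA' puts a gap in the first (row) sequence, 'GB' in the second.
    Rows are vectorized; the within-row horizontal-gap recursion is solved
    by a running-maximum over gap-opening candidates."""
    n, m = S.shape
    M = np.full(m + 1, NEG)
    GA = np.full(m + 1, NEG)
    GB = np.full(m + 1, NEG)
    M[0] = 0.0
    if m:
        GA[1:] = go + ge * np.arange(1, m + 1)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrA = np.ones((n + 1, m + 1), dtype=np.int8)
    ptrB = np.full((n + 1, m + 1), 2, dtype=np.int8)
    ptrA[0, 1] = 0
    jj = np.arange(m)

    for i in range(1, n + 1):
        Mp, GAp, GBp = M, GA, GB
        M = np.full(m + 1, NEG)
        GA = np.full(m + 1, NEG)
        GB = np.full(m + 1, NEG)
        # substitution state: diagonal from any predecessor state
        stack = np.stack([Mp[:-1], GAp[:-1], GBp[:-1]])
        best = stack.max(axis=0)
        M[1:] = S[i - 1] + best
        ptrM[i, 1:] = stack.argmax(axis=0)
        # vertical gap (gap in second sequence, consumes row unit i)
        stack = np.stack([Mp + go + ge, GAp + go + ge, GBp + ge])
        GB[:] = stack.max(axis=0)
        ptrB[i] = stack.argmax(axis=0)
        GB[0] = go + ge * i
        ptrB[i, 0] = 0 if i == 1 else 2
        # horizontal gap via running max over opening candidates
        if m:
            src = np.maximum(M[:-1], GB[:-1])
            run = np.maximum.accumulate(src + go - ge * jj)
            GA[1:] = ge * np.arange(1, m + 1) + run
            open_val = src + go + ge
            ext_val = np.concatenate(([NEG], GA[1:-1])) + ge if m > 1 else np.array([NEG])
            opened = open_val >= ext_val - 1e-9
            ptrA[i, 1:] = np.where(
                opened, np.where(M[:-1] >= GB[:-1], 0, 2), 1
            )
    finals = [M[m], GA[m], GB[m]]
    state = int(np.argmax(finals))
    score = finals[state]

    ops: list[str] = []
    i, j = n, m
    names = ("M", "GA", "GB")
    ptrs = (ptrM, ptrA, ptrB)
    while i > 0 or j > 0:
        ops.append(names[state])
        prev = int(ptrs[state][i, j])
        if state == 0:
            i, j = i - 1, j - 1
        elif state == 1:
            j -= 1
        else:
            i -= 1
        state = prev
    ops.reverse()
    return float(score), ops


def pairwise_global_align(a: str, b: str, params: AlignParams | None = None
                          ) -> tuple[str, str, float]:
    """Optimal global alignment of two proteins; returns (aligned_a,
    aligned_b, score)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    params = params or AlignParams()
    mat, index = params.matrix()
    ea, eb = _encode(a, index, "first sequence"), _encode(b, index, "second sequence")
    S = mat[np.ix_(ea, eb)]
    score, ops = _nw_core(S, params.gap_open, params.gap_extend)
    out_a, out_b = [], []
    i = j = 0
    for op in ops:
        if op == "M":
            out_a.append(a[i]); out_b.append(b[j]); i += 1; j += 1
        elif op == "GA":
            out_a.append("-"); out_b.append(b[j]); j += 1
        else:
            out_a.append(a[i]); out_b.append("-"); i += 1
    return "".join(out_a), "".join(out_b), score


# ----------------------------------------------------------------- progressive
def _profile(rows: list[np.ndarray], n_letters: int) -> np.ndarray:
    """Column residue frequencies (gaps excluded from counts but included in
    the divisor, so gappy columns score proportionally less)."""
    L = len(rows[0])
    prof = np.zeros((L, n_letters))
    for row in rows:
        mask = row >= 0
        prof[np.arange(L)[mask], row[mask]] += 1.0
    return prof / len(rows)


def _merge(group_a, group_b, mat, go, ge):
    """Profile-profile NW; existing gaps are preserved (once a gap, always
    a gap)."""
    rows_a = [r for _, r in group_a]
    rows_b = [r for _, r in group_b]
    pa = _profile(rows_a, mat.shape[0])
    pb = _profile(rows_b, mat.shape[0])
    S = (pa @ mat) @ pb.T
    _, ops = _nw_core(S, go, ge)
    idx_a, idx_b = [], []
    i = j = 0
    for op in ops:
        if op == "M":
            idx_a.append(i); idx_b.append(j); i += 1; j += 1
        elif op == "GA":
            idx_a.append(-1); idx_b.append(j); j += 1
        else:
            idx_a.append(i); idx_b.append(-1); i += 1

    def expand(row: np.ndarray, idx: list[int]) -> np.ndarray:
        out = np.full(len(idx), -1, dtype=np.int32)
        sel = [k for k, v in enumerate(idx) if v >= 0]
        out[sel] = row[[idx[k] for k in sel]]
        return out

    merged = [(t, expand(r, idx_a)) for t, r in group_a]
    merged += [(t, expand(r, idx_b)) for t, r in group_b]
    return merged


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    k = min(k, len(a), len(b))
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 1.0
    return 1.0 - len(ka & kb) / denom


def progressive_align(seqs: dict[str, str], params: AlignParams | None = None,
                      gene_name: str = "gene") -> ProteinAlignment:
    """Progressive MSA: k-mer distances -> UPGMA guide tree -> leaf-to-root
    profile merging.  Deterministic given input order and params."""
    if not seqs:
        raise ValueError("no sequences to align")
    params = params or AlignParams()
    mat, index = params.matrix()
    taxa = list(seqs)
    if len(taxa) == 1:
        return ProteinAlignment(gene_name, dict(seqs))
    for t, s in seqs.items():
        if not s:
            raise ValueError(f"{gene_name}/{t}: empty sequence")

    clusters: dict[int, list] = {
        i: [(t, _encode(seqs[t], index, f"{gene_name}/{t}"))]
        for i, t in enumerate(taxa)
    }
    if len(taxa) == 2:
        order = [(0, 1)]
    else:
        n = len(taxa)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = _kmer_distance(seqs[taxa[i]], seqs[taxa[j]])
        Z = linkage(squareform(dm, checks=False), method="average")
        order = [(int(a), int(b)) for a, b, _, _ in Z]

    next_id = len(taxa)
    for a, b in order:
        clusters[next_id] = _merge(clusters.pop(a), clusters.pop(b),
                                   mat, params.gap_open, params.gap_extend)
        next_id += 1
    (final,) = clusters.values()

    by_taxon = dict(final)
    rows_arr = [by_taxon[t] for t in taxa]
    keep = ~np.all(np.stack(rows_arr) < 0, axis=0)  # drop all-gap columns
    alphabet = {i: c for c, i in index.items()}
    rows = {}
    for t in taxa:
        arr = by_taxon[t][keep]
        rows[t] = "".join("-" if v < 0 else alphabet[int(v)] for v in arr)
    return ProteinAlignment(gene_name, rows)
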