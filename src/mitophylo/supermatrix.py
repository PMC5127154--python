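"""Codon supermatrix construction.

The core steps of mitogenome supermatrix phylogenomics: retrotranslate each
per-gene protein alignment back into codons using every taxon's original
CDS, then concatenate the 13 codon alignments (in canonical genome order)
into one partitioned nucleotide matrix.  Working at the protein level and
back-translating keeps the nucleotide alignment codon-aware: every gap is a
multiple of three and every row gap-strips to the taxon's coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genes import CANONICAL_PCGS, translate_mito
from .msa import ProteinAlignment


@dataclass
class PartitionMap:
    """Ordered per-gene column ranges, 1-based inclusive, jointly covering
    1..L with no gaps or overlaps."""

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        expected = 1
        for gene, start, end in self.entries:
            if start != expected or end < start:
                raise ValueError(
                    f"partition {gene} [{start},{end}] breaks contiguous coverage "
                    f"(expected start {expected})"
                )
            expected = end + 1

    @property
    def total_length(self) -> int:
        return self.entries[-1][2] if self.entries else 0

    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]


@dataclass
class CodonAlignment:
    """A back-translated (codon-level nucleotide) alignment for one gene."""

    gene_name: str
    rows: dict[str, str]
    n_cols: int = 0

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_name}: unequal row lengths")
        self.n_cols = lengths.pop()
        if self.n_cols % 3:
            raise ValueError(f"{self.gene_name}: width {self.n_cols} not codon-sized")


@dataclass
class CodonSupermatrix:
    """Concatenated codon alignment over all genes with its partition map."""

    taxa: list[str]
    matrix: dict[str, str]
    partitions: PartitionMap
    occupancy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        L = self.partitions.total_length
        for taxon in self.taxa:
            if len(self.matrix[taxon]) != L:
                raise ValueError(f"{taxon}: row length != partition total {L}")
        if not self.occupancy:
            self.occupancy = {
                t: 1.0 - self.matrix[t].count("-") / L if L else 0.0
                for t in self.taxa
            }

    @property
    def columns(self) -> int:
        return self.partitions.total_length

    def gene_block(self, gene: str) -> dict[str, str]:
        for g, start, end in self.partitions.entries:
            if g == gene:
                return {t: self.matrix[t][start - 1:end] for t in self.taxa}
        raise KeyError(gene)


class BacktranslationError(ValueError):
    pass


def backtranslate(aln: ProteinAlignment, cds_by_taxon: dict[str, str]
                  ) -> CodonAlignment:
    """Expand a protein alignment into codons using each taxon's CDS.

    Residue columns become the source codon in reading order, gaps become
    ``---`` and X residues emit the original (N-containing) codon.  Each
    taxon's CDS must translate to exactly its gap-stripped row."""
    rows: dict[str, str] = {}
    for taxon, aligned in aln.rows.items():
        if taxon not in cds_by_taxon:
            raise BacktranslationError(f"{aln.gene_name}/{taxon}: no CDS supplied")
        cds = cds_by_taxon[taxon].upper()
        stripped = aligned.replace("-", "")
        if len(cds) != 3 * len(stripped):
            raise BacktranslationError(
                f"{aln.gene_name}/{taxon}: CDS length {len(cds)} does not match "
                f"{len(stripped)} aligned residues"
            )
        translated = translate_mito(cds) if cds else ""
        for k, (exp, got) in enumerate(zip(stripped, translated)):
            if exp != got:
                raise BacktranslationError(
                    f"{aln.gene_name}/{taxon}: protein/CDS mismatch at residue "
                    f"{k + 1} (alignment has {exp}, CDS translates to {got})"
                )
        out = []
        pos = 0
        for char in aligned:
            if char == "-":
                out.append("---")
            else:
                out.append(cds[3 * pos:3 * pos + 3])
                pos += 1
        rows[taxon] = "".join(out)
    return CodonAlignment(aln.gene_name, rows)


def concatenate(gene_alignments: list[CodonAlignment],
                gene_order: tuple[str, ...] = CANONICAL_PCGS
                ) -> CodonSupermatrix:
    """Concatenate codon alignments into a supermatrix.

    Genes are placed in ``gene_order`` (canonical genome order by default;
    alignments for genes outside the order follow, in input order).  A taxon
    absent from a gene receives an all-gap block there."""
    if not gene_alignments:
        raise ValueError("no gene alignments to concatenate")
    by_gene = {a.gene_name: a for a in gene_alignments}
    if len(by_gene) != len(gene_alignments):
        raise ValueError("duplicate gene names in input alignments")
    ordered = [by_gene[g] for g in gene_order if g in by_gene]
    ordered += [a for a in gene_alignments if a.gene_name not in gene_order]

    taxa = sorted({t for a in ordered for t in a.rows})
    entries = []
    pos = 1
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    for aln in ordered:
        entries.append((aln.gene_name, pos, pos + aln.n_cols - 1))
        pos += aln.n_cols
        for t in taxa:
            pieces[t].append(aln.rows.get(t, "-" * aln.n_cols))
    matrix = {t: "".join(pieces[t]) for t in taxa}
    return CodonSupermatrix(taxa=taxa, matrix=matrix,
                            partitions=PartitionMap(entries))


def supermatrix_report(matrix: CodonSupermatrix) -> pd.DataFrame:
    """Per-taxon occupancy and base composition plus a TOTAL row; per-gene
    partition lengths are carried in the attrs."""
    rows = []
    for taxon in matrix.taxa:
        seq = matrix.matrix[taxon]
        non_gap = [c for c in seq if c != "-"]
        n = len(non_gap) or 1
        comp = {b: non_gap.count(b) / n for b in "ACGT"}
        rows.append({"taxon": taxon, "occupancy": matrix.occupancy[taxon],
                     "non_gap_sites": len(non_gap), **comp})
    total = {"taxon": "TOTAL",
             "occupancy": sum(matrix.occupancy.values()) / len(matrix.taxa),
             "non_gap_sites": sum(r["non_gap_sites"] for r in rows)}
    for b in "ACGT":
        weight = sum(r[b] * r["non_gap_sites"] for r in rows)
        total[b] = weight / max(total["non_gap_sites"], 1)
    rows.append(total)
    df = pd.DataFrame(rows)
    df.attrs["partitions"] = [
        {"gene": g, "start": s, "end": e, "length": e - s + 1}
        for g, s, e in matrix.partitions.entries
    ]
    df.attrs["total_length"] = matrix.columns
    return df
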