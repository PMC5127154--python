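"""Mitochondrial protein-coding genes: synonym resolution, extraction,
translation under the vertebrate mitochondrial code, and gene-order
validation against the canonical teleost arrangement.

Vertebrate mitogenomes carry 13 protein-coding genes (PCGs), 22 tRNAs,
2 rRNAs and one non-coding control region (D-loop).  Translation uses NCBI
code table 2, whose departures from the standard code matter here: ATA
codes Met, TGA codes Trp, and AGA/AGG are stop codons.  Mitochondrial CDS
frequently end in an incomplete stop (T or TA) completed by
polyadenylation; such trailing partial codons are accepted and trimmed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from Bio.Data import CodonTable

from .seq_formats import GeneFeature, MitoRecord

#: the 13 canonical PCG symbols in mitochondrial genome order
CANONICAL_PCGS = ("ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
                  "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB")

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]
STOP_CODONS = frozenset(_TABLE2.stop_codons)  # TAA, TAG, AGA, AGG


class TranslationError(ValueError):
    pass


class ExtractionError(ValueError):
    pass


def _load_table(name: str) -> list[list[str]]:
    text = resources.files("mitophylo.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _normalize_key(raw: str) -> str:
    return re.sub(r"[ \-_.]", "", raw.upper())


_SYNONYMS: dict[str, str] = {
    _normalize_key(alias): canonical
    for alias, canonical in _load_table("gene_synonyms.tsv")
}

#: canonical (name, kind, strand) arrangement, starting at tRNA-Phe
CANONICAL_TELEOST_ORDER: tuple[tuple[str, str, str], ...] = tuple(
    (name, kind, strand) for name, kind, strand in _load_table("teleost_gene_order.tsv")
)


def resolve_gene_name(raw: str) -> Optional[str]:
    """Map an annotation label to its canonical symbol (None if unknown).

    Canonical values are the 13 PCG symbols, ``rrnS``/``rrnL`` and the
    ``tRNA-Xxx`` tags; resolution is case-insensitive and ignores spaces,
    dashes, underscores and periods, so ``COI``, ``co1`` and ``MT-CO1`` all
    resolve to ``COX1``.  Resolving a canonical symbol returns itself."""
    return _SYNONYMS.get(_normalize_key(raw))


# ----------------------------------------------------------------- translation
def translate_mito(cds: str, codon_start: int = 1) -> str:
    """Translate a CDS under the vertebrate mitochondrial code (table 2).

    The reading frame starts at ``codon_start`` (1-based).  A single
    terminal stop codon is trimmed; a trailing incomplete codon of 1-2 nt is
    treated as a polyadenylation-completed stop and dropped.  Codons
    containing N translate to X.  An internal stop codon raises
    :class:`TranslationError` with the codon index."""
    if not cds:
        raise TranslationError("empty coding sequence")
    if codon_start not in (1, 2, 3):
        raise ValueError(f"codon_start must be 1..3, got {codon_start}")
    seq = cds.upper()[codon_start - 1:]
    n_full = len(seq) // 3
    if n_full == 0:
        raise TranslationError("coding sequence shorter than one codon")
    protein = []
    for i in range(n_full):
        codon = seq[3 * i:3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_full - 1:
                break  # terminal stop, trimmed (trailing partial nt dropped too)
            raise TranslationError(f"internal stop codon {codon} at codon {i + 1}")
        if "N" in codon:
            protein.append("X")
        else:
            aa = _TABLE2.forward_table.get(codon)
            if aa is None:
                raise TranslationError(f"untranslatable codon {codon!r} at codon {i + 1}")
            protein.append(aa)
    return "".join(protein)


def effective_cds(cds: str, codon_start: int = 1) -> str:
    """Frame-adjusted CDS with terminal stop (complete or incomplete) and any
    trailing partial codon removed; its length is 3x the protein length."""
    protein = translate_mito(cds, codon_start)
    seq = cds.upper()[codon_start - 1:]
    return seq[:3 * len(protein)]


# ------------------------------------------------------------------ extraction
@dataclass
class GeneSet:
    """The 13 PCGs extracted from one mitogenome.

    ``genes`` maps each present symbol to its (frame-adjusted, stop-trimmed)
    CDS and protein; symbols with no annotated CDS appear in ``missing``."""

    taxon: str
    genes: dict[str, tuple[str, str]] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)

    def __post_init__(self):
        bad = set(self.genes) - set(CANONICAL_PCGS)
        if bad:
            raise ValueError(f"non-canonical gene symbols: {sorted(bad)}")
        covered = sorted(list(self.genes) + list(self.missing))
        if covered != sorted(CANONICAL_PCGS):
            raise ValueError("genes + missing must cover the 13 PCGs exactly once")
        for name, (cds, protein) in self.genes.items():
            if len(cds) != 3 * len(protein):
                raise ValueError(f"{self.taxon}/{name}: CDS/protein length mismatch")


def extract_pcgs(record: MitoRecord) -> GeneSet:
    """Pull the 13 protein-coding genes out of an annotated mitogenome.

    Slices by feature coordinates, reverse-complements minus-strand genes,
    honors ``codon_start``, and translates under the feature's code table
    (2 unless annotated otherwise).  A symbol annotated twice is an error;
    unannotated symbols are reported as missing."""
    genes: dict[str, tuple[str, str]] = {}
    for feat in record.features:
        if feat.feature_kind != "CDS":
            continue
        symbol = resolve_gene_name(feat.gene_name)
        if symbol not in CANONICAL_PCGS:
            continue
        if symbol in genes:
            raise ExtractionError(
                f"{record.accession}: duplicate CDS annotation for {symbol}"
            )
        raw = record.feature_sequence(feat)
        if len(raw) < 3:
            raise ExtractionError(
                f"{record.accession}/{symbol}: CDS shorter than one codon"
            )
        try:
            protein = translate_mito(raw, feat.codon_start)
        except TranslationError as exc:
            raise ExtractionError(f"{record.accession}/{symbol}: {exc}") from exc
        cds = raw.upper()[feat.codon_start - 1:][:3 * len(protein)]
        genes[symbol] = (cds, protein)
    missing = [s for s in CANONICAL_PCGS if s not in genes]
    return GeneSet(taxon=record.organism or record.accession,
                   genes=genes, missing=missing)


# ------------------------------------------------------------------ gene order
@dataclass
class GeneOrderReport:
    observed_order: list[tuple[str, str, str]]
    deviations: list[str]
    counts: tuple[int, int, int, int]  # (n_pcg, n_trna, n_rrna, n_dloop)

    @property
    def is_canonical(self) -> bool:
        return not self.deviations


def validate_gene_order(record: MitoRecord) -> GeneOrderReport:
    """Compare a record's feature arrangement to the canonical teleost order.

    The observed feature list (rotated so tRNA-Phe comes first, since the
    genome is circular) is compared position-by-position against the
    canonical 37-gene table; every name, kind or strand mismatch becomes one
    deviation line.  Counts are reported regardless."""
    observed: list[tuple[str, str, str]] = []
    for feat in record.features:
        if feat.feature_kind == "D-loop":
            name = "D-loop"
        else:
            name = resolve_gene_name(feat.gene_name) or f"?{feat.gene_name}"
        observed.append((name, feat.feature_kind, feat.strand))

    kinds = [kind for _, kind, _ in observed]
    counts = (kinds.count("CDS"), kinds.count("tRNA"),
              kinds.count("rRNA"), kinds.count("D-loop"))

    names = [name for name, _, _ in observed]
    if "tRNA-Phe" in names:
        pivot = names.index("tRNA-Phe")
        rotated = observed[pivot:] + observed[:pivot]
    else:
        rotated = list(observed)

    deviations: list[str] = []
    canonical = CANONICAL_TELEOST_ORDER
    if len(rotated) != len(canonical):
        deviations.append(
            f"feature count {len(rotated)} differs from canonical {len(canonical)}"
        )
        extra = {n for n, _, _ in rotated} - {n for n, _, _ in canonical}
        absent = {n for n, _, _ in canonical} - {n for n, _, _ in rotated}
        if extra:
            deviations.append(f"unexpected features: {sorted(extra)}")
        if absent:
            deviations.append(f"absent features: {sorted(absent)}")
    else:
        for i, ((on, ok, os), (cn, ck, cs)) in enumerate(zip(rotated, canonical)):
            if on != cn:
                deviations.append(f"position {i + 1}: found {on}, expected {cn}")
            elif ok != ck:
                deviations.append(f"{on}: kind {ok}, expected {ck}")
            elif os != cs:
                deviations.append(f"{on}: strand {os}, expected {cs}")
    return GeneOrderReport(observed_order=observed, deviations=deviations,
                           counts=counts)
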