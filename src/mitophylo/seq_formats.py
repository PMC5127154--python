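"""On-disk formats: GenBank flat files, FASTA, relaxed PHYLIP, NEXUS, RAxML
partition files and Newick.

GenBank and FASTA parsing/writing are delegated to Biopython behind the
package's own record types.  Coordinates are 1-based inclusive everywhere at
this interface, matching the GenBank convention; features located with
``join(...)`` across the circular origin carry ``wraps_origin=True``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqRecord import SeqRecord

from .trees import PhyloTree, read_newick, write_newick  # noqa: F401  (re-export)

if TYPE_CHECKING:  # pragma: no cover
    from .supermatrix import CodonSupermatrix

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "D-loop")

_VALID_NT = set("ACGTN")
_AMBIGUITY = set("RYSWKMBDHV")


class GenBankParseError(ValueError):
    pass


class SequenceValidationError(ValueError):
    pass


@dataclass
class GeneFeature:
    """One annotated gene on a mitogenome (1-based inclusive coordinates)."""

    gene_name: str
    feature_kind: str
    start: int
    end: int
    strand: str = "+"
    transl_table: int = 2
    codon_start: int = 1
    wraps_origin: bool = False

    def __post_init__(self):
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.codon_start not in (1, 2, 3):
            raise ValueError(f"codon_start must be 1..3, got {self.codon_start}")
        if not self.wraps_origin and self.start > self.end:
            raise ValueError(
                f"{self.gene_name}: start {self.start} > end {self.end} "
                "on a non-wrapping feature"
            )

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return (genome_length - self.start + 1) + self.end
        return self.end - self.start + 1


@dataclass
class MitoRecord:
    """One annotated mitogenome: sequence plus ordered gene features."""

    accession: str
    organism: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    is_circular: bool = True

    def __post_init__(self):
        self.sequence = normalize_nucleotides(self.sequence, context=self.accession)
        for feat in self.features:
            hi = max(feat.start, feat.end)
            if feat.start < 1 or hi > self.length_bp:
                raise ValueError(
                    f"{self.accession}/{feat.gene_name}: coordinates "
                    f"[{feat.start},{feat.end}] outside 1..{self.length_bp}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Genomic slice for a feature, reverse-complemented for '-' strand."""
        if feat.wraps_origin:
            raw = self.sequence[feat.start - 1:] + self.sequence[:feat.end]
        else:
            raw = self.sequence[feat.start - 1:feat.end]
        if feat.strand == "-":
            raw = str(Seq(raw).reverse_complement())
        return raw


def normalize_nucleotides(seq: str, context: str = "") -> str:
    """Upcase; map IUPAC ambiguity codes to N (logged); reject other letters."""
    seq = seq.upper().replace("U", "T")
    letters = set(seq)
    bad = letters - _VALID_NT - _AMBIGUITY
    if bad:
        raise SequenceValidationError(
            f"{context}: invalid sequence characters {sorted(bad)}"
        )
    amb = letters & _AMBIGUITY
    if amb:
        logger.warning("%s: ambiguity codes %s mapped to N", context, sorted(amb))
        seq = re.sub("[" + "".join(sorted(_AMBIGUITY)) + "]", "N", seq)
    return seq


# --------------------------------------------------------------------- GenBank
_KIND_TO_GB = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "D-loop"}
_GB_TO_KIND = {v: k for k, v in _KIND_TO_GB.items()}


def read_genbank(path) -> list[MitoRecord]:
    """Parse a GenBank flat file into one MitoRecord per LOCUS entry."""
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenBankParseError(f"{path}: {exc}") from exc
    for rec in parsed:
        records.append(_convert_genbank_record(rec, path))
    return records


def _convert_genbank_record(rec: SeqRecord, path) -> MitoRecord:
    seq_len = len(rec.seq)
    features: list[GeneFeature] = []
    for feat in rec.features:
        kind = _GB_TO_KIND.get(feat.type)
        if kind is None:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or [feat.type])[0]
        try:
            start, end, wraps = _location_bounds(feat.location, seq_len)
        except ValueError as exc:
            raise GenBankParseError(
                f"{path}:{rec.id}/{name}: malformed location ({exc})"
            ) from exc
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(GeneFeature(
            gene_name=name,
            feature_kind=kind,
            start=start,
            end=end,
            strand=strand,
            transl_table=int((quals.get("transl_table") or [2])[0]),
            codon_start=int((quals.get("codon_start") or [1])[0]),
            wraps_origin=wraps,
        ))
    topology = rec.annotations.get("topology", "circular")
    return MitoRecord(
        accession=rec.id if rec.id != "<unknown id>" else rec.name,
        organism=rec.annotations.get("organism", rec.description or ""),
        sequence=str(rec.seq),
        features=features,
        is_circular=(topology == "circular"),
    )


def _location_bounds(location, seq_len: int) -> tuple[int, int, bool]:
    """Biopython (0-based half-open) location -> 1-based inclusive bounds."""
    parts = getattr(location, "parts", [location])
    if len(parts) == 1:
        return int(location.start) + 1, int(location.end), False
    if len(parts) == 2:
        a, b = parts
        if int(a.end) == seq_len and int(b.start) == 0:
            return int(a.start) + 1, int(b.end), True
    raise ValueError(f"unsupported compound location {location}")


def write_genbank(records: list[MitoRecord], path) -> None:
    """Write records in a GenBank dialect sufficient for lossless re-reading."""
    out = []
    for rec in records:
        seqrec = SeqRecord(
            Seq(rec.sequence),
            id=rec.accession,
            name=re.sub(r"[^A-Za-z0-9_]", "_", rec.accession)[:16] or "RECORD",
            description=rec.organism,
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if rec.is_circular else "linear",
                "organism": rec.organism,
                "accessions": [rec.accession.split(".")[0]],
            },
        )
        for feat in rec.features:
            strand = -1 if feat.strand == "-" else 1
            if feat.wraps_origin:
                loc = CompoundLocation([
                    SimpleLocation(feat.start - 1, rec.length_bp, strand),
                    SimpleLocation(0, feat.end, strand),
                ])
            else:
                loc = SimpleLocation(feat.start - 1, feat.end, strand)
            quals = {"gene": [feat.gene_name]}
            if feat.feature_kind == "CDS":
                quals["transl_table"] = [str(feat.transl_table)]
                quals["codon_start"] = [str(feat.codon_start)]
            seqrec.features.append(
                SeqFeature(loc, type=_KIND_TO_GB[feat.feature_kind], qualifiers=quals)
            )
        out.append(seqrec)
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "genbank")


# ----------------------------------------------------------------------- FASTA
def read_fasta(path, upcase: bool = True) -> dict[str, str]:
    """FASTA -> ordered {id: sequence}; duplicate ids are an error."""
    seqs: dict[str, str] = {}
    dupes = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split(None, 1)[0]
            if name in seqs:
                dupes.append(name)
            seqs[name] = seq.upper() if upcase else seq
    if dupes:
        raise ValueError(f"{path}: duplicate FASTA ids: {sorted(set(dupes))}")
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ----------------------------------------------------- supermatrix serializers
def write_supermatrix(matrix: "CodonSupermatrix", fmt: str, path) -> Path:
    """Write the concatenated alignment plus a sibling RAxML partition file.

    ``fmt`` is one of phylip (relaxed: full names, whitespace-delimited),
    fasta, or nexus (DATA block + SETS block with one charset per gene).
    Returns the partition-file path."""
    path = Path(path)
    if fmt == "fasta":
        write_fasta({t: matrix.matrix[t] for t in matrix.taxa}, path)
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(matrix.taxa)} {matrix.columns}\n")
            for taxon in matrix.taxa:
                fh.write(f"{_safe_name(taxon)}  {matrix.matrix[taxon]}\n")
    elif fmt == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.columns};\n")
            fh.write("    FORMAT DATATYPE=DNA MISSING=N GAP=-;\n    MATRIX\n")
            for taxon in matrix.taxa:
                fh.write(f"    {_safe_name(taxon)}  {matrix.matrix[taxon]}\n")
            fh.write("    ;\nEND;\n\nBEGIN SETS;\n")
            for gene, start, end in matrix.partitions.entries:
                fh.write(f"    CHARSET {gene} = {start}-{end};\n")
            fh.write("END;\n")
    else:
        raise ValueError(f"unknown supermatrix format {fmt!r}")
    part_path = path.with_suffix(path.suffix + ".partitions")
    with open(part_path, "w") as fh:
        for gene, start, end in matrix.partitions.entries:
            fh.write(f"DNA, {gene} = {start}-{end}\n")
    return part_path


def _safe_name(name: str) -> str:
    return re.sub(r"\s+", "_", name)


def read_alignment_fasta(path) -> dict[str, str]:
    """Aligned FASTA -> {taxon: row}; all rows must share one length."""
    rows = read_fasta(path)
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: rows have unequal lengths {sorted(lengths)}")
    return {t: s.replace("?", "-") for t, s in rows.items()}
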