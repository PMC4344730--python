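"""Sequence and annotation input/output.

All external formats (FASTA, GenBank flat file, BED, GFF3, Clustal) are read
and written here, and region extraction with GenBank-style coordinates is
confined to this module so the rest of the pipeline never handles raw files
or coordinate conventions.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  All user-facing coordinates —
``Region``, BED/GFF3 round-trips, GenBank citations — are expressed in the
convention of the respective standard: ``Region`` is 1-based inclusive
(GenBank style; ``start > end`` denotes the reverse complement of the
forward span), BED is 0-based half-open, GFF3 is 1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

__all__ = [
    "GenomicSequence",
    "Region",
    "ParseError",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "extract_region",
    "write_annotations",
    "read_bed",
    "read_gff3",
    "read_clustal",
    "write_clustal",
]

# IUPAC nucleotide one-letter codes (uppercase), including N and gaps excluded.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


def reverse_complement(s: str) -> str:
    """Reverse complement of an IUPAC DNA string (ambiguity codes mapped)."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicSequence:
    """An identified DNA sequence.

    Residues are stored uppercase and restricted to IUPAC DNA codes;
    ambiguity codes (including N) are retained, never converted.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise ParseError(
                f"sequence {self.id!r} contains non-IUPAC residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "GenomicSequence":
        return GenomicSequence(self.id, reverse_complement(self.residues), self.description)


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive region on a named sequence.

    ``start > end`` is legal and denotes the reverse complement of the
    forward span ``[end, start]`` (GenBank citation style, e.g.
    "positions 1429 to 1179").
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if min(self.start, self.end) < 1:
            raise ValueError(f"coordinates must be >= 1, got {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def is_reverse(self) -> bool:
        return self.start > self.end or self.strand == "-"

    @property
    def span(self) -> tuple[int, int]:
        """Forward-strand 1-based inclusive (low, high)."""
        return (min(self.start, self.end), max(self.start, self.end))

    def __len__(self) -> int:
        return abs(self.start - self.end) + 1


# ---------------------------------------------------------------------------
# FASTA / GenBank
# ---------------------------------------------------------------------------

def _validate_fasta_lines(path: Path) -> None:
    """Line-level validation so parse errors can name the offending line."""
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                seen_header = True
                if len(line) == 1:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
            else:
                if not seen_header:
                    raise ParseError(f"{path}:{lineno}: sequence data before first header")
                bad = set(line.upper()) - IUPAC_DNA
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal residue(s) {sorted(bad)}"
                    )


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a FASTA file into a list of :class:`GenomicSequence`.

    Order is preserved; duplicate record ids are rejected.  Malformed headers
    or illegal residues raise :class:`ParseError` naming the line number.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(GenomicSequence(rec.id, str(rec.seq), desc))
    return records


def write_fasta(seqs: Iterable[GenomicSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id}" + (f" {s.description}" if s.description else "")
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_genbank(path: str | Path) -> list[GenomicSequence]:
    """Read GenBank flat file(s); only LOCUS/DEFINITION/ORIGIN are used.

    Feature tables are deliberately ignored — downstream stages need the
    sequence and its identifier only.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "genbank"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomicSequence(rec.id, str(rec.seq), rec.description))
    return records


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def extract_region(seq: GenomicSequence, region: Region) -> GenomicSequence:
    """Extract a region; reversed coordinates return the reverse complement.

    The returned length is always ``|start - end| + 1``.
    """
    lo, hi = region.span
    if hi > len(seq):
        raise IndexError(
            f"region {region.start}..{region.end} out of bounds for "
            f"{seq.id!r} of length {len(seq)}"
        )
    sub = seq.residues[lo - 1 : hi]
    if region.is_reverse:
        sub = reverse_complement(sub)
    new_id = f"{seq.id}:{region.start}-{region.end}"
    return GenomicSequence(new_id, sub, seq.description)


# ---------------------------------------------------------------------------
# Annotation output (BED / GFF3) and round-trip readers
# ---------------------------------------------------------------------------

#: (seq_id, 1-based start, 1-based end, name, score, strand, feature_type)
AnnotationRow = tuple[str, int, int, str, float, str, str]


def _annotation_rows(annos) -> list[AnnotationRow]:
    rows = []
    for a in annos:
        # duck-typed: accepts HelitronAnnotation-likes or raw Region + name
        region = a.element if hasattr(a, "element") else a
        name = getattr(a, "name", getattr(a, "tier", "feature"))
        score = float(getattr(a, "score", 0.0))
        ftype = getattr(a, "feature_type", "helitron")
        lo, hi = region.span
        strand = "-" if region.is_reverse else "+"
        rows.append((region.seq_id, lo, hi, str(name), score, strand, ftype))
    return rows


def write_annotations(annos, path: str | Path, format: str = "BED") -> None:
    """Write annotations as BED (0-based half-open) or GFF3 (1-based).

    Round-tripping through :func:`read_bed` / :func:`read_gff3` preserves
    all coordinates exactly.
    """
    fmt = format.upper()
    if fmt not in {"BED", "GFF3"}:
        raise ValueError(f"unknown annotation format {format!r} (use BED or GFF3)")
    rows = _annotation_rows(annos)
    with open(path, "w") as fh:
        if fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for seq_id, lo, hi, name, score, strand, ftype in rows:
                fh.write(
                    f"{seq_id}\thelhunt\t{ftype}\t{lo}\t{hi}\t{score:g}\t{strand}\t.\tID={name}\n"
                )
        else:
            fh.write('track name="helhunt"\n')
            for seq_id, lo, hi, name, score, strand, ftype in rows:
                fh.write(f"{seq_id}\t{lo - 1}\t{hi}\t{name}\t{score:g}\t{strand}\n")


def read_bed(path: str | Path) -> list[AnnotationRow]:
    """Read a BED file back to 1-based inclusive annotation rows."""
    rows: list[AnnotationRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            seq_id, start0, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "feature"
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((seq_id, start0 + 1, end, name, score, strand, "helitron"))
    return rows


def read_gff3(path: str | Path) -> list[AnnotationRow]:
    """Read a GFF3 file back to 1-based inclusive annotation rows."""
    rows: list[AnnotationRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            seq_id, _src, ftype, lo, hi, score, strand = parts[:7]
            attrs = parts[8] if len(parts) > 8 else ""
            name = "feature"
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    name = kv[3:]
            rows.append(
                (seq_id, int(lo), int(hi), name, float(score) if score != "." else 0.0, strand, ftype)
            )
    return rows


# ---------------------------------------------------------------------------
# Clustal alignments (for the alignment module)
# ---------------------------------------------------------------------------

def read_clustal(path: str | Path) -> list[tuple[str, str]]:
    aln = AlignIO.read(str(path), "clustal")
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def write_clustal(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(gapped), id=name, description="") for name, gapped in rows]
    )
    AlignIO.write(msa, str(path), "clustal")
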