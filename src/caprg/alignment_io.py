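"""Readers, writers and placed-read conversion for FASTA / SAM / BED / TSV.

Coordinates are 1-based, fully closed intervals internally (the SAM
convention); the BED writer is the single point where they are converted to
0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGTN")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: CIGAR operators that consume reference bases.
_REF_CONSUMING = frozenset("MDN=X")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending record."""


class SamParseError(ValueError):
    """Raised for malformed SAM input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, uppercased on ingest."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id}: invalid bases {sorted(bad)} "
                "(allowed: A,C,G,T,N)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM alignment line (primary or secondary), possibly unmapped.

    ``seq`` holds the read bases exactly as stored in the SAM record, i.e.
    in aligned orientation (reverse-complemented relative to the sequencer
    output when ``strand`` is "-").
    """

    read_id: str
    is_mapped: bool
    chrom: str = ""
    pos: int = 0
    cigar: str = ""
    mapq: int = 0
    strand: str = "+"
    seq: str = ""

    def __post_init__(self) -> None:
        if self.is_mapped and (not self.chrom or self.pos < 1 or not self.cigar):
            raise ValueError(
                f"mapped record {self.read_id}: chrom/pos/cigar must be set"
            )
        if not 0 <= self.mapq <= 254:
            raise ValueError(f"record {self.read_id}: mapq {self.mapq} out of range")
        if self.strand not in ("+", "-"):
            raise ValueError(f"record {self.read_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class AlignedRead:
    """A read with its single selected reference placement.

    ``seq`` holds the read bases as sequenced (original read orientation);
    :func:`caprg.olc_assembler.orient_read` maps it back into reference
    orientation for window-level assembly.
    """

    read_id: str
    seq: str
    chrom: str
    pos: int
    ref_span: int
    strand: str
    mapq: int

    def __post_init__(self) -> None:
        if self.pos < 1 or self.ref_span < 1:
            raise ValueError(
                f"read {self.read_id}: pos/ref_span must be >= 1 "
                f"(got {self.pos}, {self.ref_span})"
            )

    def end(self) -> int:
        """Rightmost reference base covered (1-based, inclusive)."""
        return self.pos + self.ref_span - 1


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; line wrapping is irrelevant. A record with an
    empty sequence or a disallowed character raises :class:`FastaParseError`
    naming the record.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
        except ValueError as exc:
            raise FastaParseError(str(exc)) from exc
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60
) -> None:
    """Write records as FASTA with the given line wrap (round-trip safe)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string.

    M, D, N, = and X consume reference; I, S, H and P do not.
    """
    if not cigar or cigar == "*":
        raise ValueError(f"CIGAR {cigar!r} has no reference span")
    span = 0
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        consumed += len(m.group(0))
        if m.group(2) in _REF_CONSUMING:
            span += int(m.group(1))
    if consumed != len(cigar):
        raise ValueError(f"invalid CIGAR string: {cigar!r}")
    return span


def read_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Yield every record of a SAM file, including secondary alignments.

    Unmapped records are yielded with ``is_mapped=False`` so callers can
    account for them; strand is decoded from flag bit 0x10. ``seq`` is the
    SAM-stored (aligned-orientation) sequence.
    """
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise SamParseError(f"{path}: {exc}") from exc
    with sam:
        for aln in sam:
            if aln.is_unmapped:
                yield AlignmentRecord(
                    read_id=aln.query_name,
                    is_mapped=False,
                    mapq=min(aln.mapping_quality, 254),
                    seq=(aln.query_sequence or "").upper(),
                )
                continue
            yield AlignmentRecord(
                read_id=aln.query_name,
                is_mapped=True,
                chrom=aln.reference_name,
                pos=aln.reference_start + 1,
                cigar=aln.cigarstring or "*",
                mapq=min(aln.mapping_quality, 254),
                strand="-" if aln.is_reverse else "+",
                seq=(aln.query_sequence or "").upper(),
            )


def aligned_read_from_record(record: AlignmentRecord) -> AlignedRead:
    """Convert a mapped :class:`AlignmentRecord` into an :class:`AlignedRead`.

    The SAM-stored sequence of a "-"-strand record is reverse-complemented so
    that ``AlignedRead.seq`` is always the read as it came off the sequencer.
    """
    if not record.is_mapped:
        raise ValueError(f"cannot place unmapped read {record.read_id}")
    seq = record.seq
    if record.strand == "-":
        seq = reverse_complement(seq)
    return AlignedRead(
        read_id=record.read_id,
        seq=seq,
        chrom=record.chrom,
        pos=record.pos,
        ref_span=cigar_reference_span(record.cigar),
        strand=record.strand,
        mapq=record.mapq,
    )


def write_placed_tsv(reads: Iterable[AlignedRead], path: str | Path) -> None:
    """Write placed reads as TSV: read_id, chrom, pos, ref_span, strand, mapq, seq."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tpos\tref_span\tstrand\tmapq\tseq\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.pos}\t{r.ref_span}\t"
                f"{r.strand}\t{r.mapq}\t{r.seq}\n"
            )


def read_placed_tsv(path: str | Path) -> list[AlignedRead]:
    """Read back the TSV written by :func:`write_placed_tsv`."""
    reads: list[AlignedRead] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            reads.append(
                AlignedRead(
                    read_id=f[idx["read_id"]],
                    chrom=f[idx["chrom"]],
                    pos=int(f[idx["pos"]]),
                    ref_span=int(f[idx["ref_span"]]),
                    strand=f[idx["strand"]],
                    mapq=int(f[idx["mapq"]]),
                    seq=f[idx["seq"]],
                )
            )
    return reads
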