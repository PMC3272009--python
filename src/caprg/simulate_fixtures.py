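"""Synthetic genomes, planted transcripts, anchored reads and truth SAM.

The generator emulates the study conditions the pipeline targets: long
single-end 454-style reads (~100-500 bp, low error) sequenced from
transcribed loci of a genome closely related to the mapping reference.
The truth SAM stands in for the aligner, so the whole pipeline is
exercisable offline; the error model is substitution-only by default
(454's characteristic homopolymer indels are available as an optional
small indel rate to exercise the banded overlapper).

All randomness flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from caprg.alignment_io import (
    AlignmentRecord,
    SequenceRecord,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthLocus:
    """A planted transcribed locus: where it sits and what it transcribes.

    ``seq`` is the transcript sequence (reverse-complemented relative to
    the genome for "-"-strand loci); coordinates are 1-based closed.
    """

    transcript_id: str
    chrom: str
    start: int
    length: int
    strand: str
    seq: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.length < 1:
            raise ValueError(f"{self.transcript_id}: invalid start/length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def generate_genome(
    n_chrom: int, chrom_lengths: Sequence[int], seed: int
) -> list[SequenceRecord]:
    """Uniform-random ACGT chromosomes, deterministic under ``seed``."""
    if n_chrom != len(chrom_lengths):
        raise ValueError("n_chrom must equal len(chrom_lengths)")
    if any(length < 1 for length in chrom_lengths):
        raise ValueError("chromosome lengths must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i, length in enumerate(chrom_lengths, start=1):
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        records.append(SequenceRecord(id=f"chr{i}", seq=seq))
    return records


def plant_transcripts(
    genome: Sequence[SequenceRecord],
    n: int,
    length_range: tuple[int, int] = (400, 800),
    min_gap: int = 200,
    strand_mix: float = 0.5,
    seed: int = 0,
) -> list[TruthLocus]:
    """Plant ``n`` non-overlapping transcribed loci across the genome.

    Loci are spread round-robin over chromosomes and packed left to right
    with at least ``min_gap`` bases between neighbours; an infeasible
    packing raises rather than silently truncating. ``strand_mix`` is the
    fraction of "-"-strand loci in expectation.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad length_range {length_range}")
    per_chrom: dict[str, list[int]] = {g.id: [] for g in genome}
    chrom_ids = [g.id for g in genome]
    for i in range(n):
        per_chrom[chrom_ids[i % len(chrom_ids)]].append(i)

    chrom_seq = {g.id: g.seq for g in genome}
    loci: list[TruthLocus] = []
    for chrom in chrom_ids:
        idxs = per_chrom[chrom]
        if not idxs:
            continue
        lengths = rng.integers(lo, hi + 1, size=len(idxs))
        needed = int(lengths.sum()) + min_gap * (len(idxs) + 1)
        clen = len(chrom_seq[chrom])
        if needed > clen:
            raise ValueError(
                f"cannot pack {len(idxs)} loci totalling {lengths.sum()} bp "
                f"with gaps >= {min_gap} into {chrom} ({clen} bp)"
            )
        # distribute the slack randomly among the n+1 gaps
        slack = clen - int(lengths.sum()) - min_gap * (len(idxs) + 1)
        cuts = np.sort(rng.integers(0, slack + 1, size=len(idxs)))
        extra = np.diff(np.concatenate(([0], cuts)))
        pos = 1
        for k, i in enumerate(idxs):
            pos += min_gap + int(extra[k])
            length = int(lengths[k])
            strand = "-" if rng.random() < strand_mix else "+"
            sub = chrom_seq[chrom][pos - 1 : pos - 1 + length]
            loci.append(
                TruthLocus(
                    transcript_id=f"t{i + 1:03d}",
                    chrom=chrom,
                    start=pos,
                    length=length,
                    strand=strand,
                    seq=reverse_complement(sub) if strand == "-" else sub,
                )
            )
            pos += length
    return sorted(loci, key=lambda t: t.transcript_id)


def _mutate(
    frag: str, error_rate: float, indel_rate: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Apply substitutions (and optional indels) to a reference-oriented
    fragment; returns (mutated sequence, CIGAR)."""
    out: list[str] = []
    ops: list[str] = []
    for base in frag:
        r = rng.random()
        if indel_rate > 0 and r < indel_rate / 2:
            ops.append("D")  # deletion: reference base skipped in the read
            continue
        if indel_rate > 0 and r < indel_rate:
            out.append("ACGT"[rng.integers(0, 4)])
            ops.append("I")
        if error_rate > 0 and rng.random() < error_rate:
            alts = [b for b in "ACGT" if b != base]
            out.append(alts[rng.integers(0, 3)])
        else:
            out.append(base)
        ops.append("M")
    # run-length encode the op string
    cigar = []
    prev, count = None, 0
    for op in ops:
        if op == prev:
            count += 1
        else:
            if prev is not None:
                cigar.append(f"{count}{prev}")
            prev, count = op, 1
    cigar.append(f"{count}{prev}")
    return "".join(out), "".join(cigar)


def simulate_reads(
    loci: Sequence[TruthLocus],
    genome: Sequence[SequenceRecord],
    coverage: float,
    read_len_range: tuple[int, int] = (100, 500),
    error_rate: float = 0.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    revcomp_prob: float = 0.5,
) -> tuple[list[SequenceRecord], list[AlignmentRecord]]:
    """Draw reads uniformly along each locus until coverage is reached.

    Read lengths are uniform in ``read_len_range`` (capped at the locus
    length); each read is sequenced from either cDNA strand with
    probability ``revcomp_prob`` of flipping, so window members arrive on
    mixed strands as they would from a real library. Truth records carry
    the chromosomal position, CIGAR, strand (flag 0x10 semantics) and a
    high mapping quality; SAM convention stores the read bases in aligned
    (reference) orientation.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be within [0, 0.1]")
    rng = np.random.default_rng(seed)
    chrom_seq = {g.id: g.seq for g in genome}
    lo, hi = read_len_range
    reads: list[SequenceRecord] = []
    truth: list[AlignmentRecord] = []
    for locus in loci:
        if locus.chrom not in chrom_seq:
            raise ValueError(f"{locus.transcript_id}: unknown chromosome")
        target = coverage * locus.length
        sampled = 0
        k = 0
        while sampled < target:
            k += 1
            length = int(rng.integers(lo, hi + 1))
            length = min(length, locus.length)
            # Read midpoints are uniform over the locus and reads that would
            # overhang are clamped to the boundary, mimicking the pile-up of
            # cDNA reads at transcript termini; interior coverage stays
            # uniform while both ends remain sampled.
            mid = int(rng.integers(0, locus.length))
            offset = min(max(mid - length // 2, 0), locus.length - length)
            gpos = locus.start + offset
            frag = chrom_seq[locus.chrom][gpos - 1 : gpos - 1 + length]
            mutated, cigar = _mutate(frag, error_rate, indel_rate, rng)
            flip = rng.random() < revcomp_prob
            strand = locus.strand
            if flip:
                strand = "-" if strand == "+" else "+"
            read_id = f"{locus.transcript_id}_r{k:04d}"
            truth.append(
                AlignmentRecord(
                    read_id=read_id,
                    is_mapped=True,
                    chrom=locus.chrom,
                    pos=gpos,
                    cigar=cigar,
                    mapq=60,
                    strand=strand,
                    seq=mutated,  # aligned (reference) orientation
                )
            )
            as_sequenced = (
                reverse_complement(mutated) if strand == "-" else mutated
            )
            reads.append(SequenceRecord(id=read_id, seq=as_sequenced))
            sampled += len(mutated)
    return reads, truth


def write_truth_sam(
    truth: Sequence[AlignmentRecord],
    genome: Sequence[SequenceRecord],
    path: str | Path,
) -> None:
    """Emit a text SAM with @SQ lines for the genome and one line per read."""
    known = {g.id: len(g.seq) for g in genome}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in known.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in truth:
            if rec.chrom not in known:
                raise ValueError(
                    f"truth read {rec.read_id} references unknown "
                    f"chromosome {rec.chrom!r}"
                )
            flag = 16 if rec.strand == "-" else 0
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.chrom}\t{rec.pos}\t{rec.mapq}\t"
                f"{rec.cigar}\t*\t0\t0\t{rec.seq}\t*\n"
            )


def tile_reads(
    loci: Sequence[TruthLocus],
    genome: Sequence[SequenceRecord],
    read_length: int = 200,
    overlap: int = 50,
) -> tuple[list[SequenceRecord], list[AlignmentRecord]]:
    """Deterministic error-free reads tiling each locus end to end.

    Adjacent reads overlap by exactly ``overlap`` bases and the last read
    is right-aligned to the locus end, so every planted transcript is
    wholly reconstructible from its tile set.
    """
    if not 0 < overlap < read_length:
        raise ValueError("need 0 < overlap < read_length")
    chrom_seq = {g.id: g.seq for g in genome}
    reads: list[SequenceRecord] = []
    truth: list[AlignmentRecord] = []
    step = read_length - overlap
    for locus in loci:
        length = min(read_length, locus.length)
        offsets = list(range(0, max(locus.length - length, 0) + 1, step))
        if offsets[-1] != locus.length - length:
            offsets.append(locus.length - length)
        for k, off in enumerate(offsets, start=1):
            gpos = locus.start + off
            frag = chrom_seq[locus.chrom][gpos - 1 : gpos - 1 + length]
            read_id = f"{locus.transcript_id}_tile{k:03d}"
            truth.append(
                AlignmentRecord(
                    read_id=read_id,
                    is_mapped=True,
                    chrom=locus.chrom,
                    pos=gpos,
                    cigar=f"{length}M",
                    mapq=60,
                    strand=locus.strand,
                    seq=frag,
                )
            )
            as_sequenced = (
                reverse_complement(frag) if locus.strand == "-" else frag
            )
            reads.append(SequenceRecord(id=read_id, seq=as_sequenced))
    return reads, truth


@dataclass(frozen=True)
class Fixture:
    """A complete synthetic dataset: genome, truth loci, reads, truth SAM
    records."""

    genome: list[SequenceRecord]
    loci: list[TruthLocus]
    reads: list[SequenceRecord]
    truth: list[AlignmentRecord]


def make_fixture(
    n_transcripts: int = 10,
    coverage: float = 8.0,
    error_rate: float = 0.005,
    indel_rate: float = 0.0,
    seed: int = 42,
    n_chrom: int = 2,
    chrom_length: int = 25_000,
    length_range: tuple[int, int] = (400, 800),
    min_gap: int = 200,
    strand_mix: float = 0.5,
    read_len_range: tuple[int, int] = (100, 500),
) -> Fixture:
    """The default study-condition fixture: 10 transcripts of 400-800 bp on
    two 25 kb chromosomes, 8x coverage of 100-500 bp reads at 0.5%
    substitution error. Three sub-seeds derived from ``seed`` drive genome,
    planting and reads independently."""
    sub = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]
    genome = generate_genome(n_chrom, [chrom_length] * n_chrom, seeds[0])
    loci = plant_transcripts(
        genome, n_transcripts, length_range, min_gap, strand_mix, seeds[1]
    )
    reads, truth = simulate_reads(
        loci, genome, coverage, read_len_range, error_rate, indel_rate, seeds[2]
    )
    return Fixture(genome=genome, loci=loci, reads=reads, truth=truth)
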