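import numpy as np
import pytest

from caprg.alignment_io import AlignedRead, AlignmentRecord
from caprg.simulate_fixtures import (
    Fixture,
    generate_genome,
    make_fixture,
    plant_transcripts,
    tile_reads,
)


def make_aligned(read_id, pos, span, chrom="chr1", strand="+", mapq=60, seq=None):
    """AlignedRead helper; sequence content is irrelevant to binning tests."""
    return AlignedRead(
        read_id=read_id,
        seq=seq if seq is not None else "A" * span,
        chrom=chrom,
        pos=pos,
        ref_span=span,
        strand=strand,
        mapq=mapq,
    )


def make_record(read_id, chrom="chr1", pos=100, mapq=30, strand="+",
                cigar="50M", seq="A" * 50, mapped=True):
    if not mapped:
        return AlignmentRecord(read_id=read_id, is_mapped=False, mapq=0, seq=seq)
    return AlignmentRecord(
        read_id=read_id, is_mapped=True, chrom=chrom, pos=pos,
        cigar=cigar, mapq=mapq, strand=strand, seq=seq,
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def default_fixture() -> Fixture:
    """The study-condition dataset: 10 transcripts, 8x, 0.5% substitutions."""
    return make_fixture(seed=42)


@pytest.fixture(scope="session")
def tiled_dataset():
    """Error-free reads tiling 10 planted transcripts with 50 bp overlaps."""
    genome = generate_genome(2, [25_000, 25_000], seed=11)
    loci = plant_transcripts(genome, 10, seed=12)
    reads, truth = tile_reads(loci, genome, read_length=200, overlap=50)
    return genome, loci, reads, truth
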