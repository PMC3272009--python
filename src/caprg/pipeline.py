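"""End-to-end driver: SAM records in, filtered contigs and metrics out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from caprg.alignment_io import AlignedRead, AlignmentRecord, SequenceRecord, read_alignments
from caprg.olc_assembler import Contig, greedy_assemble, orient_read, rescue_assemble
from caprg.placement import PlacementReport, select_unique_placements
from caprg.postprocess_report import (
    AssemblyStats,
    assembly_stats,
    binned_assembly_rate,
    filter_contigs,
)
from caprg.windowing import Window, bin_reads, sort_placed_reads


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, pre- and post-filter."""

    placed: list[AlignedRead]
    report: PlacementReport
    windows: list[Window]
    window_contigs: list[Contig]  # unfiltered window-pass contigs
    rescue_contigs: list[Contig]
    singlets: list[str]  # read ids left unassembled after both passes
    kept: list[Contig]  # post length-filter contigs (both passes)
    dropped: list[Contig]
    stats: AssemblyStats
    assembled_reads: int
    binned_reads: int
    binned_rate: float | None

    @property
    def all_contigs(self) -> list[Contig]:
        return self.window_contigs + self.rescue_contigs


def run_pipeline(
    records: Iterable[AlignmentRecord] | str | Path,
    min_mapq: int = 1,
    tie_policy: str = "exclude",
    bin_mode: str = "max_end",
    window_min_overlap: int = 20,
    rescue_min_overlap: int = 40,
    min_identity: float = 0.90,
    min_contig_len: int = 200,
    max_gap_band: int = 5,
) -> PipelineResult:
    """Run placement, binning, window assembly, rescue and filtering.

    ``records`` may be a SAM path or an iterable of
    :class:`AlignmentRecord`. Window assembly co-orients members with the
    reference and joins at >= ``min_identity`` over >=
    ``window_min_overlap`` columns; reads from one-member windows and
    window singlets enter the rescue pass at ``rescue_min_overlap``.
    The final assembly keeps contigs strictly longer than
    ``min_contig_len``.
    """
    if isinstance(records, (str, Path)):
        records = read_alignments(records)
    placed, report = select_unique_placements(
        records, min_mapq=min_mapq, tie_policy=tie_policy
    )
    by_id = {r.read_id: r for r in placed}
    windows = bin_reads(sort_placed_reads(placed), mode=bin_mode)

    window_contigs: list[Contig] = []
    rescue_pool: list[SequenceRecord] = []
    for w in windows:
        members = [by_id[rid] for rid in w.members]
        if len(members) == 1:
            r = members[0]
            rescue_pool.append(SequenceRecord(id=r.read_id, seq=r.seq))
            continue
        oriented = [
            SequenceRecord(id=r.read_id, seq=orient_read(r)) for r in members
        ]
        contigs, singlet_ids = greedy_assemble(
            oriented,
            min_overlap=window_min_overlap,
            min_identity=min_identity,
            max_gap_band=max_gap_band,
            id_prefix=f"{w.window_id}_",
            source=f"window:{w.window_id}",
        )
        window_contigs.extend(contigs)
        for rid in singlet_ids:
            rescue_pool.append(SequenceRecord(id=rid, seq=by_id[rid].seq))

    rescue_contigs, rescue_singlets = rescue_assemble(
        rescue_pool,
        min_overlap=rescue_min_overlap,
        min_identity=min_identity,
        max_gap_band=max_gap_band,
    )

    kept, dropped = filter_contigs(
        window_contigs + rescue_contigs, min_len=min_contig_len
    )
    stats = assembly_stats(
        kept,
        n_singlets_excluded=len(rescue_singlets),
        n_below_min_len=len(dropped),
    )
    assembled, binned, rate = binned_assembly_rate(windows, window_contigs)
    return PipelineResult(
        placed=placed,
        report=report,
        windows=windows,
        window_contigs=window_contigs,
        rescue_contigs=rescue_contigs,
        singlets=sorted(rescue_singlets),
        kept=kept,
        dropped=dropped,
        stats=stats,
        assembled_reads=assembled,
        binned_reads=binned,
        binned_rate=rate,
    )
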