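"""Reduce multi-placement alignments to one placement per read.

A long read may align to several chromosomal positions with different
mapping qualities; only the placement with strictly maximal MAPQ is kept,
so each retained read represents a unique locus. Ties at the maximum are
not unique and are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from caprg.alignment_io import AlignedRead, AlignmentRecord, aligned_read_from_record

TiePolicy = Literal["exclude", "keep_first"]


@dataclass(frozen=True)
class PlacementReport:
    """Partition of the input read set by placement outcome.

    ``n_reads_in == n_placed + n_excluded_ambiguous + n_excluded_low_mapq
    + n_unmapped`` always holds; reads are counted once each, by read id.
    """

    n_reads_in: int
    n_placed: int
    n_excluded_ambiguous: int
    n_excluded_low_mapq: int
    n_unmapped: int

    def __post_init__(self) -> None:
        total = (
            self.n_placed
            + self.n_excluded_ambiguous
            + self.n_excluded_low_mapq
            + self.n_unmapped
        )
        if total != self.n_reads_in:
            raise ValueError(
                f"placement report does not partition the input: "
                f"{self.n_reads_in} != {total}"
            )


def select_unique_placements(
    records: Iterable[AlignmentRecord],
    min_mapq: int = 1,
    tie_policy: TiePolicy = "exclude",
) -> tuple[list[AlignedRead], PlacementReport]:
    """Keep at most one placement per read, by maximum mapping quality.

    Parameters
    ----------
    records
        Alignment records in any order; grouped by ``read_id`` internally.
        Secondary alignments participate in the maximum.
    min_mapq
        Reads whose best MAPQ is below this are excluded. The default of 1
        drops MAPQ-0 records, which conventionally mark ambiguous placement.
    tie_policy
        ``"exclude"`` drops a read whose maximal MAPQ is shared by two or
        more placements (a tie is not a unique locus); ``"keep_first"``
        keeps the first such placement in input order.

    Returns
    -------
    (placed, report)
        Placed reads in first-seen input order, one per read id, and a
        :class:`PlacementReport` partitioning the input read set.
    """
    if tie_policy not in ("exclude", "keep_first"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")

    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)

    placed: list[AlignedRead] = []
    n_ambiguous = n_low = n_unmapped = 0
    for read_id, recs in by_read.items():
        mapped = [r for r in recs if r.is_mapped]
        if not mapped:
            n_unmapped += 1
            continue
        best_mapq = max(r.mapq for r in mapped)
        if best_mapq < min_mapq:
            n_low += 1
            continue
        best = [r for r in mapped if r.mapq == best_mapq]
        if len(best) > 1 and tie_policy == "exclude":
            n_ambiguous += 1
            continue
        placed.append(aligned_read_from_record(best[0]))

    report = PlacementReport(
        n_reads_in=len(by_read),
        n_placed=len(placed),
        n_excluded_ambiguous=n_ambiguous,
        n_excluded_low_mapq=n_low,
        n_unmapped=n_unmapped,
    )
    return placed, report
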