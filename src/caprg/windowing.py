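"""Window binning: chain anchor-sorted placed reads into assembly bins.

Reads are sorted per chromosome by their anchor position and swept left to
right. The first read opens a window whose boundary is its rightmost
reference base; each subsequent read whose start lies at or before the
boundary joins the window, otherwise it opens a new one. Two boundary
semantics are provided:

``max_end``
    the boundary is the running maximum of member ends — standard interval
    chaining, so a long early read keeps the window open across short
    members it spans (default);
``prev_read``
    the boundary is always the previous read's end, which can split a
    window that an earlier long read still covers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from caprg.alignment_io import AlignedRead

BinMode = Literal["max_end", "prev_read"]


@dataclass
class Window:
    """A chromosome-anchored bin of reads — the unit of assembly.

    Coordinates are 1-based closed; ``start`` is the minimum member
    position and ``boundary`` the rightmost extent reached under the
    active binning mode.
    """

    window_id: str
    chrom: str
    start: int
    boundary: int
    members: list[str]

    @property
    def end(self) -> int:
        return self.boundary

    def __len__(self) -> int:
        return len(self.members)


def sort_placed_reads(
    reads: Iterable[AlignedRead],
) -> dict[str, list[AlignedRead]]:
    """Group placed reads by chromosome, each group ascending by position.

    Ties in position are broken by read id so the ordering (and everything
    downstream) is deterministic.
    """
    by_chrom: dict[str, list[AlignedRead]] = {}
    for read in reads:
        by_chrom.setdefault(read.chrom, []).append(read)
    return {
        chrom: sorted(group, key=lambda r: (r.pos, r.read_id))
        for chrom, group in sorted(by_chrom.items())
    }


def bin_reads(
    sorted_reads: Mapping[str, Sequence[AlignedRead]],
    mode: BinMode = "max_end",
) -> list[Window]:
    """Sweep each chromosome and chain reads into windows.

    Parameters
    ----------
    sorted_reads
        Output of :func:`sort_placed_reads`. Unsorted input raises
        ``ValueError`` — the chaining rule is only correct on sorted input.
    mode
        Boundary semantics; see the module docstring.

    Returns
    -------
    Windows ordered by (chromosome, start); every read lands in exactly
    one window, and a read starting exactly on the boundary base joins the
    window (closed coordinates: that base is shared).
    """
    if mode not in ("max_end", "prev_read"):
        raise ValueError(f"unknown binning mode {mode!r}")
    windows: list[Window] = []
    for chrom, reads in sorted_reads.items():
        prev_key = None
        current: Window | None = None
        ordinal = 0
        for read in reads:
            key = (read.pos, read.read_id)
            if prev_key is not None and key < prev_key:
                raise ValueError(
                    f"reads on {chrom} are not sorted by (pos, read_id): "
                    f"{key} after {prev_key}"
                )
            prev_key = key
            if current is not None and read.pos <= current.boundary:
                current.members.append(read.read_id)
                if mode == "max_end":
                    current.boundary = max(current.boundary, read.end())
                else:
                    current.boundary = read.end()
            else:
                ordinal += 1
                current = Window(
                    window_id=f"{chrom}_w{ordinal}",
                    chrom=chrom,
                    start=read.pos,
                    boundary=read.end(),
                    members=[read.read_id],
                )
                windows.append(current)
    return windows


def windows_to_bed(windows: Iterable[Window], path: str | Path) -> None:
    """Write windows as BED6: 0-based half-open, name=id, score=member count."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.chrom}\t{w.start - 1}\t{w.boundary}\t"
                f"{w.window_id}\t{len(w.members)}\t+\n"
            )


def write_bins_tsv(windows: Iterable[Window], path: str | Path) -> None:
    """Write window membership as TSV: window_id, chrom, start, end, read_id."""
    with open(path, "w") as fh:
        fh.write("window_id\tchrom\tstart\tend\tread_id\n")
        for w in windows:
            for read_id in w.members:
                fh.write(
                    f"{w.window_id}\t{w.chrom}\t{w.start}\t{w.boundary}\t{read_id}\n"
                )
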