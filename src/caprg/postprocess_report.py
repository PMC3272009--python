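"""Output filtering and assembly evaluation metrics.

Implements the evaluation side of the pipeline: the length filter applied
to finished assemblies (singlets and short contigs excluded), contig count
and mean-length statistics (N50 is deliberately not computed — it is not
comparable across assemblies), the redundancy index over tabular homology
hits, reciprocal best hits, the per-chromosome contig distribution, and
the fraction of binned reads that assembled into contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from caprg.olc_assembler import Contig
from caprg.windowing import Window

#: Standard 12 tabular homology-search columns (outfmt 6).
HIT_COLUMNS = [
    "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular homology search."""

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.query_id}")


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    mean_length: float | None  # None when no contigs survive
    total_bases: int
    n_singlets_excluded: int
    n_below_min_len: int


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse tab-separated homology hits; extra columns are ignored."""
    with open(path) as fh:
        width = max(
            (len(line.rstrip("\n").split("\t"))
             for line in fh if line.strip() and not line.startswith("#")),
            default=0,
        )
    df = pd.read_csv(
        str(path), sep="\t", header=None, comment="#", names=range(width)
    )
    if df.shape[1] < 12:
        raise ValueError(
            f"{path}: expected >=12 tab-separated columns, got {df.shape[1]}"
        )
    df = df.iloc[:, :12]
    df.columns = HIT_COLUMNS
    return [HitRecord(**row) for row in df.to_dict("records")]


def filter_contigs(
    contigs: Sequence[Contig], min_len: int = 200
) -> tuple[list[Contig], list[Contig]]:
    """Keep contigs strictly longer than ``min_len`` (201 bp is the
    smallest kept at the default); singlets never reach this stage by type
    construction. Returns (kept, dropped); counts are conserved."""
    if min_len < 0:
        raise ValueError(f"min_len must be >= 0, got {min_len}")
    kept = [c for c in contigs if len(c.seq) > min_len]
    dropped = [c for c in contigs if len(c.seq) <= min_len]
    return kept, dropped


def assembly_stats(
    contigs: Sequence[Contig],
    n_singlets_excluded: int = 0,
    n_below_min_len: int = 0,
) -> AssemblyStats:
    """Contig count, mean length and total bases of a finished assembly."""
    total = sum(len(c.seq) for c in contigs)
    mean = total / len(contigs) if contigs else None
    return AssemblyStats(
        n_contigs=len(contigs),
        mean_length=mean,
        total_bases=total,
        n_singlets_excluded=n_singlets_excluded,
        n_below_min_len=n_below_min_len,
    )


def _best_hits(
    hits: Iterable[HitRecord], evalue_cutoff: float
) -> dict[str, HitRecord]:
    """Best passing hit per query: lowest e-value, ties by highest
    bitscore, then first occurrence. The cutoff is strict (evalue < cutoff)."""
    best: dict[str, tuple[float, float, int, HitRecord]] = {}
    for i, h in enumerate(hits):
        if not h.evalue < evalue_cutoff:
            continue
        key = (h.evalue, -h.bitscore, i)
        if h.query_id not in best or key < best[h.query_id][:3]:
            best[h.query_id] = (h.evalue, -h.bitscore, i, h)
    return {q: v[3] for q, v in best.items()}


def redundancy_index(
    hits: Sequence[HitRecord],
    evalue_cutoff: float = 1e-5,
    count_mode: str = "best_hit",
) -> float | None:
    """(queries with a passing hit) / (distinct subjects among best hits).

    The index is >= 1 whenever defined and equals 1 only when every best
    hit targets a distinct subject; a higher value means more contigs map
    to the same locus. Returns None (undefined) when no hit survives the
    cutoff. ``count_mode="rows"`` counts every passing hit row in the
    numerator instead of one best hit per query (then the denominator is
    the distinct subjects among all passing rows).
    """
    if count_mode not in ("best_hit", "rows"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if count_mode == "rows":
        passing = [h for h in hits if h.evalue < evalue_cutoff]
        if not passing:
            return None
        return len(passing) / len({h.subject_id for h in passing})
    best = _best_hits(hits, evalue_cutoff)
    if not best:
        return None
    subjects = {h.subject_id for h in best.values()}
    return len(best) / len(subjects)


def reciprocal_best_hits(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    evalue_cutoff: float = 1e-5,
) -> set[tuple[str, str]]:
    """Pairs (a, b) where b is a's best passing hit in A-vs-B and a is b's
    best passing hit in B-vs-A."""
    best_ab = _best_hits(hits_ab, evalue_cutoff)
    best_ba = _best_hits(hits_ba, evalue_cutoff)
    return {
        (a, h.subject_id)
        for a, h in best_ab.items()
        if h.subject_id in best_ba and best_ba[h.subject_id].subject_id == a
    }


def chromosome_distribution(
    contigs: Sequence[Contig], windows: Sequence[Window]
) -> dict[str, int]:
    """Count window-pass contigs per chromosome.

    Rescue contigs carry no chromosome anchor by construction and are
    counted under the "unanchored" key rather than guessed onto a
    chromosome.
    """
    chrom_of = {w.window_id: w.chrom for w in windows}
    counts: dict[str, int] = {}
    for c in contigs:
        if c.source == "rescue":
            counts["unanchored"] = counts.get("unanchored", 0) + 1
            continue
        if not c.source.startswith("window:"):
            raise ValueError(f"contig {c.contig_id}: unknown source {c.source!r}")
        wid = c.source.split(":", 1)[1]
        if wid not in chrom_of:
            raise ValueError(
                f"contig {c.contig_id} references unknown window {wid!r}"
            )
        chrom = chrom_of[wid]
        counts[chrom] = counts.get(chrom, 0) + 1
    return counts


def binned_assembly_rate(
    windows: Sequence[Window], window_contigs: Sequence[Contig]
) -> tuple[int, int, float | None]:
    """Fraction of binned reads that assembled into window-pass contigs.

    Returns (assembled, binned, rate); rate is None when no read was
    binned. ``assembled <= binned`` always holds since contig members are
    drawn from window members.
    """
    binned = sum(len(w.members) for w in windows)
    assembled = sum(len(c.members) for c in window_contigs)
    if binned == 0:
        return assembled, binned, None
    return assembled, binned, assembled / binned


def write_report(
    out_dir: str | Path,
    stats: AssemblyStats,
    chrom_counts: Mapping[str, int],
    rbh_pairs: Iterable[tuple[str, str]] = (),
    redundancy: float | None = None,
    rate: tuple[int, int, float | None] | None = None,
) -> None:
    """Emit TSV tables and a plain-text summary of an assembly run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted(chrom_counts.items()), columns=["chrom", "n_contigs"]
    ).to_csv(out / "chromosome_distribution.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(rbh_pairs), columns=["a_id", "b_id"]
    ).to_csv(out / "rbh_pairs.tsv", sep="\t", index=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write(f"contigs\t{stats.n_contigs}\n")
        fh.write(f"total_bases\t{stats.total_bases}\n")
        if stats.mean_length is not None:
            fh.write(f"mean_length\t{stats.mean_length:.1f}\n")
        fh.write(f"singlets_excluded\t{stats.n_singlets_excluded}\n")
        fh.write(f"short_contigs_excluded\t{stats.n_below_min_len}\n")
        if redundancy is not None:
            fh.write(f"redundancy_index\t{redundancy:.3f}\n")
        if rate is not None and rate[2] is not None:
            fh.write(
                f"binned_assembly_rate\t{rate[0]}/{rate[1]}\t{100 * rate[2]:.1f}%\n"
            )
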