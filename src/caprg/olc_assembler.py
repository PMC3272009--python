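"""Greedy overlap-layout-consensus assembly of window reads and singlets.

Each window's reads are co-oriented with the reference, pairwise
suffix-prefix overlaps passing the identity and length thresholds are
ranked by score (identity x length), and layouts are grown greedily from
the best remaining admissible overlap. Reads wholly contained in a longer
read at the identity threshold are absorbed into their host's layout
rather than competing for dovetail joins. Consensus is a per-column
majority vote.

The window pass trusts reference co-orientation and uses the permissive
20 bp minimum overlap; the rescue pass over singlets trusts no orientation
(both strands are tried, with a shared-16-mer prefilter) and requires a
40 bp overlap.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from caprg.alignment_io import (
    AlignedRead,
    SequenceRecord,
    read_fasta,
    reverse_complement,
    write_fasta,
)

_EDLIB_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

# Tie-break order for consensus voting: A < C < G < T; N never outvotes.
_BASE_ORDER = "ACGT"


class BackendError(RuntimeError):
    """Raised when the optional external assembler backend fails or is missing."""


@dataclass(frozen=True)
class Overlap:
    """A scored suffix(a)-prefix(b) overlap between two oriented reads."""

    a_id: str
    b_id: str
    a_suffix_start: int
    length: int
    identity: float

    def __post_init__(self) -> None:
        if self.a_id == self.b_id:
            raise ValueError("overlap of a read with itself")
        if self.length < 1 or not 0.0 <= self.identity <= 1.0:
            raise ValueError(
                f"invalid overlap length={self.length} identity={self.identity}"
            )

    @property
    def score(self) -> float:
        return self.identity * self.length


@dataclass
class Layout:
    """Reads laid out by offset; at least one member sits at offset 0."""

    members: list[tuple[str, int, str]]  # (read_id, offset, oriented_seq)
    total_span: int


@dataclass(frozen=True)
class Contig:
    """A consensus sequence with >=2 member reads and its provenance."""

    contig_id: str
    seq: str
    members: tuple[str, ...]
    source: str  # "window:<window_id>" or "rescue"
    depth: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a contig requires >=2 member reads")
        if len(self.depth) != len(self.seq):
            raise ValueError("per-column depth must match consensus length")

    def __len__(self) -> int:
        return len(self.seq)


def orient_read(read: AlignedRead) -> str:
    """Return the read sequence in reference orientation.

    "+"-strand reads are returned as stored; "-"-strand reads are
    reverse-complemented, so all members of a window are co-oriented.
    """
    bad = set(read.seq) - set("ACGTN")
    if bad:
        raise ValueError(f"read {read.read_id}: non-ACGTN bases {sorted(bad)}")
    if read.strand == "-":
        return reverse_complement(read.seq)
    return read.seq


def _as_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _edlib_stats(cigar: str) -> tuple[int, int]:
    """(matches, aligned columns) from an edlib extended cigar."""
    matches = cols = 0
    for m in _EDLIB_CIGAR_RE.finditer(cigar):
        n = int(m.group(1))
        cols += n
        if m.group(2) == "=":
            matches += n
    return matches, cols


def find_best_overlap(
    a: str,
    b: str,
    min_overlap: int,
    min_identity: float,
    max_gap_band: int = 5,
    a_id: str = "a",
    b_id: str = "b",
) -> Overlap | None:
    """Best-scoring suffix(a)-prefix(b) overlap, or None below thresholds.

    Every overlap length L from min(len(a), len(b)) down to ``min_overlap``
    is scanned with mismatch-only (Hamming) scoring; identity is
    matches / aligned columns, and a gap column counts as a mismatch. When
    ``max_gap_band`` > 0, offsets whose ungapped identity fails but whose
    overlap has a well-matching end are re-aligned with a small banded
    edit-distance alignment so that isolated indels do not destroy an
    otherwise good overlap.

    The returned overlap maximizes score = identity x length, ties broken
    by longer overlap; both thresholds are >= comparisons.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    if not 0.0 < min_identity <= 1.0:
        raise ValueError(f"min_identity must be in (0, 1], got {min_identity}")
    na, nb = len(a), len(b)
    lmax = min(na, nb)
    if lmax < min_overlap:
        return None

    aa, bb = _as_u8(a), _as_u8(b)
    best: tuple[float, int, int] | None = None  # (score, length, -suffix_start)
    best_ov: Overlap | None = None
    for length in range(lmax, min_overlap - 1, -1):
        if best is not None and best[0] >= length:
            break  # no shorter overlap can outscore the current best
        suffix_start = na - length
        mism = int(np.count_nonzero(aa[suffix_start:] != bb[:length]))
        ident = (length - mism) / length
        cand: tuple[float, int, int, int] | None = None  # + columns
        if ident >= min_identity:
            cand = (ident * length, length, -suffix_start, length)
            cand_ident = ident
        elif max_gap_band > 0:
            g = min(20, length)
            head = int(np.count_nonzero(aa[suffix_start : suffix_start + g] != bb[:g]))
            tail = int(np.count_nonzero(aa[na - g :] != bb[length - g : length]))
            if min(head, tail) <= 4:
                k = int((1.0 - min_identity) * length) + max_gap_band
                res = edlib.align(
                    b[:length], a[suffix_start:], mode="NW", task="path", k=k
                )
                if res["editDistance"] >= 0:
                    matches, cols = _edlib_stats(res["cigar"])
                    gident = matches / cols
                    if gident >= min_identity and cols >= min_overlap:
                        cand = (gident * cols, cols, -suffix_start, cols)
                        cand_ident = gident
        if cand is not None:
            key = cand[:3]
            if best is None or key > best:
                best = key
                best_ov = Overlap(
                    a_id=a_id,
                    b_id=b_id,
                    a_suffix_start=suffix_start,
                    length=cand[3],
                    identity=cand_ident,
                )
    return best_ov


def _find_containment(
    host: str, small: str, min_identity: float, max_gap_band: int
) -> tuple[int, float] | None:
    """Locate ``small`` inside ``host`` at >= min_identity; (offset, identity)."""
    k = int((1.0 - min_identity) * len(small)) + max_gap_band
    res = edlib.align(small, host, mode="HW", task="path", k=k)
    if res["editDistance"] < 0:
        return None
    cigar = res["cigar"]
    # True containment needs at most a few isolated indels; a dovetail
    # overhang surfaces as many insertion columns (the small read sticking
    # out of the host), so cap total gap columns at the band width.
    ins = sum(int(n) for n, op in _EDLIB_CIGAR_RE.findall(cigar) if op == "I")
    dels = sum(int(n) for n, op in _EDLIB_CIGAR_RE.findall(cigar) if op == "D")
    if ins > max_gap_band or dels > max_gap_band:
        return None
    matches, cols = _edlib_stats(cigar)
    ident = matches / cols
    if ident < min_identity:
        return None
    return res["locations"][0][0], ident


def call_consensus(
    layout: Layout, contig_id: str, source: str
) -> Contig:
    """Majority-vote consensus over a layout's columns.

    Ties are broken in the fixed order A < C < G < T; N never outvotes a
    real base. Every column inside the span must be covered by at least
    one read (layouts built by the greedy merger are contiguous by
    construction).
    """
    if len(layout.members) < 2:
        raise ValueError("consensus requires a layout with >=2 members")
    span = layout.total_span
    # counts[:, base] per column; column 4 is N
    counts = np.zeros((span, 5), dtype=np.int32)
    base_idx = {65: 0, 67: 1, 71: 2, 84: 3, 78: 4}  # A C G T N
    lut = np.full(256, -1, dtype=np.int8)
    for code, i in base_idx.items():
        lut[code] = i
    for _read_id, offset, seq in layout.members:
        idx = lut[_as_u8(seq)]
        np.add.at(counts, (np.arange(offset, offset + len(seq)), idx), 1)
    depth = counts.sum(axis=1)
    if np.any(depth == 0):
        raise RuntimeError(
            f"layout for {contig_id} has a zero-coverage column; "
            "layouts must be contiguous"
        )
    real = counts[:, :4]
    best = real.argmax(axis=1)  # argmax is first max: A<C<G<T tie-break
    seq_arr = np.frombuffer(_BASE_ORDER.encode(), dtype=np.uint8)[best]
    # columns covered only by N keep N
    only_n = real.sum(axis=1) == 0
    seq_arr = np.where(only_n, np.uint8(78), seq_arr)
    consensus = seq_arr.tobytes().decode("ascii")
    members = tuple(sorted(m[0] for m in layout.members))
    return Contig(
        contig_id=contig_id,
        seq=consensus,
        members=members,
        source=source,
        depth=tuple(int(d) for d in depth),
    )


def _greedy_core(
    records: Sequence[tuple[str, str]],
    min_overlap: int,
    min_identity: float,
    max_gap_band: int,
    id_prefix: str,
    source: str,
) -> tuple[list[Contig], list[str]]:
    """Greedy OLC over co-oriented (read_id, seq) pairs."""
    records = sorted(records, key=lambda r: r[0])
    ids = [r[0] for r in records]
    seqs = dict(records)
    if len(ids) != len(seqs):
        raise ValueError("duplicate read ids in assembly input")

    # --- containment: absorb reads fully covered by a longer read ---
    # Host order strictly decreases (length, reversed id) so chains resolve.
    def host_key(rid: str) -> tuple[int, str]:
        return (len(seqs[rid]), rid)

    contained: dict[str, tuple[str, int]] = {}  # read -> (host, offset in host)
    for rid in ids:
        best_host: tuple[float, int, str, int] | None = None
        for hid in ids:
            if hid == rid:
                continue
            hk, rk = host_key(hid), host_key(rid)
            if not (hk[0] > rk[0] or (hk[0] == rk[0] and hk[1] < rk[1])):
                continue
            hit = _find_containment(seqs[hid], seqs[rid], min_identity, max_gap_band)
            if hit is None:
                continue
            offset, ident = hit
            key = (ident, len(seqs[hid]), hid, offset)
            if best_host is None or key > best_host:
                best_host = key
        if best_host is not None:
            contained[rid] = (best_host[2], best_host[3])

    free = [rid for rid in ids if rid not in contained]

    # --- all-pairs dovetail overlaps among free reads ---
    candidates: list[Overlap] = []
    for i in free:
        for j in free:
            if i == j:
                continue
            ov = find_best_overlap(
                seqs[i], seqs[j], min_overlap, min_identity, max_gap_band,
                a_id=i, b_id=j,
            )
            if ov is not None:
                candidates.append(ov)
    candidates.sort(key=lambda o: (-o.score, -o.length, o.a_id, o.b_id))

    # --- greedy layout merging; joins happen only at layout ends ---
    layout_of: dict[str, int] = {rid: k for k, rid in enumerate(free)}
    layouts: dict[int, Layout] = {
        k: Layout(members=[(rid, 0, seqs[rid])], total_span=len(seqs[rid]))
        for k, rid in enumerate(free)
    }

    def rightmost(lay: Layout) -> tuple[str, int, str]:
        return max(lay.members, key=lambda m: (m[1] + len(m[2]), m[0]))

    def leftmost(lay: Layout) -> tuple[str, int, str]:
        return min(lay.members, key=lambda m: (m[1], m[0]))

    for ov in candidates:
        la, lb = layout_of[ov.a_id], layout_of[ov.b_id]
        if la == lb:
            continue
        lay_a, lay_b = layouts[la], layouts[lb]
        ra = rightmost(lay_a)
        lb_left = leftmost(lay_b)
        if ra[0] != ov.a_id or lb_left[0] != ov.b_id:
            continue  # only end reads may dovetail-join
        shift = ra[1] + ov.a_suffix_start
        for rid, off, seq in lay_b.members:
            lay_a.members.append((rid, off + shift, seq))
            layout_of[rid] = la
        lay_a.total_span = max(lay_a.total_span, shift + lay_b.total_span)
        del layouts[lb]

    # --- place contained reads into their (transitive) host's layout ---
    def resolve(rid: str) -> tuple[str, int]:
        host, off = contained[rid]
        while host in contained:
            host2, off2 = contained[host]
            off += off2
            host = host2
        return host, off

    for rid in sorted(contained):
        host, off = resolve(rid)
        lk = layout_of[host]
        lay = layouts[lk]
        host_off = next(m[1] for m in lay.members if m[0] == host)
        lay.members.append((rid, host_off + off, seqs[rid]))
        layout_of[rid] = lk
        lay.total_span = max(lay.total_span, host_off + off + len(seqs[rid]))

    # --- consensus ---
    contigs: list[Contig] = []
    singlets: list[str] = []
    n = 0
    for lk in sorted(layouts, key=lambda k: leftmost(layouts[k])[0]):
        lay = layouts[lk]
        if len(lay.members) == 1:
            singlets.append(lay.members[0][0])
            continue
        n += 1
        contigs.append(call_consensus(lay, f"{id_prefix}c{n}", source))
    return contigs, singlets


def greedy_assemble(
    reads: Sequence[SequenceRecord],
    min_overlap: int = 20,
    min_identity: float = 0.90,
    max_gap_band: int = 5,
    id_prefix: str = "",
    source: str = "window:unknown",
) -> tuple[list[Contig], list[str]]:
    """Assemble co-oriented window members into contigs.

    Defaults follow the window pass: >=90% identity and >=20 bp overlap —
    identity kept stringent because reads binned to one window are expected
    to be highly identical, and the overlap minimum kept low to allow the
    maximum number of joins into longer contigs.

    Returns (contigs, singlet read ids); every input read appears in
    exactly one contig or in the singlet list.
    """
    if not reads:
        return [], []
    return _greedy_core(
        [(r.id, r.seq) for r in reads],
        min_overlap, min_identity, max_gap_band, id_prefix, source,
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def rescue_assemble(
    singlet_reads: Sequence[SequenceRecord],
    min_overlap: int = 40,
    min_identity: float = 0.90,
    max_gap_band: int = 5,
    prefilter_k: int = 16,
    id_prefix: str = "rescue_",
) -> tuple[list[Contig], list[str]]:
    """Second assembly pass over singly-windowed and unassembled reads.

    No reference co-orientation is trusted across windows, so both
    orientations of every read are considered. Candidate pairs are limited
    to reads sharing an exact ``prefilter_k``-mer in either relative
    orientation (any 40 bp overlap at >=90% identity with at most 2 errors
    per 40 bp contains an exact 16-mer by pigeonhole). Contigs get
    source="rescue"; the default 40 bp minimum overlap is stricter than
    the window pass because genomic anchoring no longer vouches for the
    joins.
    """
    if not singlet_reads:
        return [], []
    reads = sorted(singlet_reads, key=lambda r: r.id)
    seqs = {r.id: r.seq for r in reads}
    if len(seqs) != len(reads):
        raise ValueError("duplicate read ids in rescue input")
    ids = [r.id for r in reads]

    # k-mer prefilter: candidate pairs share a k-mer in some orientation
    fwd = {rid: _kmer_set(seqs[rid], prefilter_k) for rid in ids}
    rc_seq = {rid: reverse_complement(seqs[rid]) for rid in ids}
    rev = {rid: _kmer_set(rc_seq[rid], prefilter_k) for rid in ids}
    pairs: list[tuple[str, str, bool]] = []  # (i, j, same_orientation)
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            i, j = ids[x], ids[y]
            if fwd[i] & fwd[j]:
                pairs.append((i, j, True))
            if fwd[i] & rev[j]:
                pairs.append((i, j, False))

    # score each candidate pair and record the relative orientation of the
    # best passing join (dovetail either direction, or containment)
    edges: list[tuple[float, str, str, bool]] = []
    for i, j, same in pairs:
        sj = seqs[j] if same else rc_seq[j]
        best = 0.0
        for a, b in ((seqs[i], sj), (sj, seqs[i])):
            ov = find_best_overlap(
                a, b, min_overlap, min_identity, max_gap_band, a_id="x", b_id="y"
            )
            if ov is not None:
                best = max(best, ov.score)
        if best == 0.0 and len(seqs[i]) != len(sj):
            host, small = (seqs[i], sj) if len(seqs[i]) > len(sj) else (sj, seqs[i])
            if len(small) >= min_overlap:
                hit = _find_containment(host, small, min_identity, max_gap_band)
                if hit is not None:
                    best = hit[1] * len(small)
        if best > 0.0:
            edges.append((best, i, j, same))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))

    # union-find with orientation parity; conflicting edges are dropped
    parent: dict[str, str] = {rid: rid for rid in ids}
    parity: dict[str, int] = {rid: 0 for rid in ids}  # flip relative to root

    def find2(rid: str) -> tuple[str, int]:
        p = 0
        while parent[rid] != rid:
            p ^= parity[rid]
            rid = parent[rid]
        return rid, p

    for _score, i, j, same in edges:
        ri, pi = find2(i)
        rj, pj = find2(j)
        want = 0 if same else 1  # relative flip between i and j
        if ri == rj:
            continue  # keep first (best) spanning edges; conflicts ignored
        # attach rj under ri with parity so that flip(i) ^ flip(j) == want
        parent[rj] = ri
        parity[rj] = pi ^ pj ^ want

    groups: dict[str, list[tuple[str, int]]] = {}
    for rid in ids:
        root, p = find2(rid)
        groups.setdefault(root, []).append((rid, p))

    contigs: list[Contig] = []
    singlets: list[str] = []
    n_group = 0
    for root in sorted(groups):
        members = groups[root]
        if len(members) == 1:
            singlets.append(members[0][0])
            continue
        n_group += 1
        oriented = [
            (rid, seqs[rid] if p == 0 else rc_seq[rid]) for rid, p in members
        ]
        group_contigs, group_singlets = _greedy_core(
            oriented, min_overlap, min_identity, max_gap_band,
            id_prefix=f"{id_prefix}g{n_group}_", source="rescue",
        )
        contigs.extend(group_contigs)
        singlets.extend(group_singlets)
    # renumber contigs into a flat deterministic series
    renumbered = [
        Contig(
            contig_id=f"{id_prefix}c{k + 1}",
            seq=c.seq,
            members=c.members,
            source=c.source,
            depth=c.depth,
        )
        for k, c in enumerate(contigs)
    ]
    return renumbered, sorted(singlets)


def assemble_with_external_backend(
    reads: Sequence[SequenceRecord],
    identity_percent: int = 90,
    min_overlap: int = 20,
    backend_path: str = "cap3",
    source: str = "external",
) -> tuple[list[Contig], list[str]]:
    """Assemble with an external CAP3-compatible backend.

    Writes the reads to a temporary FASTA, invokes
    ``cap3 <fasta> -p <identity_percent> -o <min_overlap>`` and parses the
    ``.cap.contigs`` / ``.cap.singlets`` outputs (membership from the
    ``.cap.ace`` layout). The behavioral contract matches
    :func:`greedy_assemble`; consensus sequences may differ at tie columns.
    """
    if not reads:
        return [], []
    exe = shutil.which(backend_path)
    if exe is None:
        raise BackendError(
            f"external assembler {backend_path!r} not found on PATH; "
            "use the internal greedy assembler instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "reads.fasta"
        write_fasta(reads, fasta)
        proc = subprocess.run(
            [exe, str(fasta), "-p", str(identity_percent), "-o", str(min_overlap)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise BackendError(
                f"{backend_path} exited with {proc.returncode}: {proc.stderr}"
            )
        contig_recs = read_fasta(f"{fasta}.cap.contigs")
        singlet_recs = read_fasta(f"{fasta}.cap.singlets")
        members = _parse_ace_membership(Path(f"{fasta}.cap.ace"))
    contigs = []
    for k, rec in enumerate(contig_recs):
        mem = tuple(sorted(members.get(rec.id, ())))
        if len(mem) < 2:
            raise BackendError(
                f"backend contig {rec.id} has {len(mem)} members in the ACE layout"
            )
        contigs.append(
            Contig(
                contig_id=f"ext_c{k + 1}",
                seq=rec.seq.replace("-", ""),
                members=mem,
                source=source,
                depth=tuple(0 for _ in rec.seq.replace("-", "")),
            )
        )
    return contigs, [r.id for r in singlet_recs]


def _parse_ace_membership(path: Path) -> dict[str, tuple[str, ...]]:
    """Contig -> member read ids from an ACE assembly file (AF lines)."""
    members: dict[str, list[str]] = {}
    if not path.exists():
        return {}
    current = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CO "):
                current = line.split()[1]
                members[current] = []
            elif line.startswith("AF ") and current is not None:
                members[current].append(line.split()[1])
    return {k: tuple(v) for k, v in members.items()}
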