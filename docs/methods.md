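# Methods

## Model and procedure

`caprg` assembles long transcriptome reads by anchoring them on a related
reference genome instead of comparing all reads against all. The underlying
assumptions are:

- a read's best genomic placement (maximal MAPQ, unique) marks the locus it
  was transcribed from, up to the divergence between the sequenced species
  and the reference;
- reads anchored to overlapping genomic intervals come from the same
  transcribed locus and are therefore nearly identical where they overlap,
  which justifies a stringent 90 % identity threshold and a permissive 20 bp
  minimum overlap inside a window;
- joins *across* windows (the rescue pass) have no genomic anchor vouching
  for them, so they must clear a longer 40 bp overlap and are tried in both
  orientations.

Coordinates are 1-based closed throughout (SAM convention); BED output is
the single point of conversion to 0-based half-open.

### Placement

All SAM records (primary and secondary) participate. Per read, the mapped
record with strictly maximal MAPQ is kept. Two policies exist for ties at
the maximum: `exclude` (default — a tie is not a unique locus) and
`keep_first` (input order). The MAPQ floor defaults to 1 because MAPQ 0
conventionally marks ambiguous placement; both the floor and the tie policy
are parameters, since neither is dictated by the mapping tool itself.
The placement report partitions the input read set exactly
(placed + ambiguous + low-MAPQ + unmapped = total), enforced by the type.

### Window binning

Reads are sorted by (position, read id) per chromosome and swept once. The
default boundary semantics, `max_end`, keep the running maximum of member
ends, which makes window membership identical to connected components of
the touching-or-overlapping interval graph (verified against an O(n²)
union-find oracle in the tests). The alternative `prev_read` uses only the
previous read's end as the boundary; it can split a window that an earlier
long read still spans, and never produces fewer windows than `max_end`.
A read starting exactly on the boundary base shares that base (closed
intervals) and joins the window. "Read length" in the boundary rule means
reference span from the CIGAR, so soft clips and indels do not distort
genomic extent; the raw-sequence-length alternative would misplace the
boundary whenever a read is clipped.

### Overlap detection

`find_best_overlap` scans every suffix(a)–prefix(b) length L from
min(len a, len b) down to the minimum overlap, scoring each with
mismatch-only (Hamming) identity; identity is matches / aligned columns,
and a gap column counts as a mismatch. The best candidate maximizes
score = identity × length, ties going to the longer overlap. Both
thresholds are ≥ comparisons: a 20-column overlap with exactly two
mismatches (identity 0.90) passes at (0.90, 20).

With `max_gap_band > 0` (default 5), an offset whose ungapped identity
fails but whose first or last 20 columns match well (≤ 4 mismatches) is
re-aligned with a banded edit-distance alignment (edlib), so a single
indel inside an otherwise clean overlap does not discard it. The gate on
well-matching ends keeps the gapped path from firing on unrelated
sequence; an indel within the first and last 20 columns simultaneously can
evade it, which is acceptable at the ≤ 0.5 % indel rates the generator
produces. With `max_gap_band=0` the scan is purely mismatch-based and
agrees exactly with an exhaustive brute-force oracle.

### Layout and consensus

Greedy assembly first absorbs **contained reads**: a read that aligns
wholly inside a longer read at ≥ 90 % identity with at most `max_gap_band`
inserted and deleted columns is attached to that host and placed at the
host's offset. The gap-column cap matters: a dovetail overhang of up to
10 % of the read can otherwise masquerade as a containment with the
overhang smeared into insertion columns, corrupting layout offsets.
Containment hosts are ordered by (length, id) so chains resolve acyclically.

Remaining reads start as singleton layouts. Candidate overlaps are sorted
by (score, length, a, b) descending and merged greedily; a merge is
admissible only between the rightmost read of one layout and the leftmost
read of another, which keeps offsets consistent by construction and keeps
every column of the merged span covered. Consensus is a per-column
majority vote; ties break in the fixed order A < C < G < T and N never
outvotes a real base. A contig requires ≥ 2 members — a single-read layout
is a singlet by definition, never a short contig.

All orderings (candidate ranking, tie-breaks, member sorting, id
assignment) are total, so a fixed input and parameters give byte-identical
output regardless of input order.

### Rescue pass

Input is the union of reads that were sole members of their window and
reads left unassembled by window-level assembly. Candidate pairs must
share an exact 16-mer in either relative orientation: any 40 bp overlap at
≥ 90 % identity with at most 2 errors per 40 bp contains an exact 16-mer
by pigeonhole, so the prefilter is lossless under the generator's error
model (a documented approximation beyond it). Relative orientations are
fixed by a parity union-find over the passing candidate edges, processed
best first; each co-oriented group then runs the same greedy core at the
40 bp threshold. Rescue contigs carry `source="rescue"` and no chromosome
anchor; reports count them under `unanchored` rather than guessing.

### External backend

`assemble_with_external_backend` wraps a CAP3-compatible executable
(`cap3 <fasta> -p <identity> -o <overlap>`), parsing its contig, singlet
and ACE layout outputs into the same `Contig` records. It exists so
fidelity questions about the internal greedy simplification can be tested
empirically when such a backend is installed; the internal assembler is
the default and carries no quality values, iterative realignment or
SNP handling.

## Evaluation metrics

- **Length filter**: strictly greater than 200 bp — a 201 bp contig is the
  shortest kept; singlets are excluded by type.
- **Binned-assembly rate**: members of window-pass contigs ÷ members of
  all windows (including one-member windows). Computed before the length
  filter, since it measures assembly success, not reporting policy.
- **Redundancy index**: queries with a passing best hit ÷ distinct
  subjects among those best hits, e-value strictly below 10⁻⁵, best hit =
  lowest e-value, ties by bitscore then first occurrence. ≥ 1 whenever
  defined; undefined (None, not 0) with no surviving hit. "Hits" counts
  queries, not HSP rows, because the index measures contigs mapping to the
  same locus; the row-count reading is available via `count_mode="rows"`.
- **Reciprocal best hits**: (a, b) such that b is a's best passing hit
  A→B and a is b's best passing hit B→A; mirror-symmetric by definition.

N50 is deliberately not computed: it is not comparable across assemblies
built from the same reads with different methods.

## Synthetic data generator

The generator emulates the intended study conditions: a reference genome
close enough that reads anchor uniquely, transcribed loci well separated
on the genome, and long low-error single-end reads.

Defaults (chosen once, as the package's study conditions):

| parameter | default | rationale |
|---|---|---|
| chromosomes | 2 × 25 kb | two reference sequences exercise per-chromosome partitioning at desk scale |
| transcripts | 10, 400–800 bp | typical partial-transcript lengths for long-read EST contigs |
| locus gap | ≥ 200 bp | guarantees windows cannot merge across loci |
| strand mix | 0.5 | both genomic strands represented |
| coverage | 8× per locus | enough depth for majority-vote consensus to cancel read errors |
| read length | uniform 100–500 bp | 454-style long reads |
| substitution rate | 0.5 % | low per-base error typical of the technology |
| indel rate | 0 (optional ≤ 0.5 %) | substitutions dominate the core tests; the optional indel rate exercises the banded overlap path |
| read MAPQ | 60 | truth placements are unique by construction |

Read midpoints are sampled uniformly over each locus and reads that would
overhang are clamped flush to the locus boundary. This mimics the pile-up
of cDNA reads at transcript termini (a cDNA fragment cannot extend past
the transcript end) and keeps both ends covered; strictly interior-uniform
starts would leave the first and last few dozen bases of every transcript
unsampled, a gap no assembler could recover. Per read, the sequencing
strand flips with probability 0.5, so windows receive mixed-strand members
and reference co-orientation is genuinely exercised.

What the generator does **not** emulate: 454 flowgram noise and
homopolymer-length errors, quality values, chimeric reads, alternative
splicing, paralogous loci, and a diverged (rather than identical)
reference. Passing tests therefore demonstrate the pipeline's mechanics —
binning, layout, consensus, accounting — under clean anchoring, not its
robustness to cross-species divergence; the truth SAM stands in for a real
long-read aligner.

`tile_reads` additionally produces deterministic, error-free reads tiling
each locus end to end with a fixed adjacent overlap; under these inputs
recovery is exact (one contig per transcript, sequence-identical), which
the tests assert.

## Numerical and design choices

- Overlap score identity × length with ties by length then id: the
  thresholds are taken as given; the ranking is this package's choice.
- Identity counts gap columns as mismatches — conservative and exactly
  testable.
- Sub-seeds for genome, planting and reads are spawned from one seed, so
  a single integer reproduces a fixture byte for byte.
- Problem sizes in the test and acceptance runs (10 transcripts, ~170
  reads, two 25 kb chromosomes, 100–500 trial oracle comparisons) are the
  package's default desk-scale study conditions; all complete in seconds.

## Known limitations

- The greedy merger joins only at layout ends; a mis-ranked early join can
  in principle block a better one (inherent to greedy OLC).
- The banded gapped-overlap gate can miss overlaps whose indels fall in
  both terminal 20-column segments.
- Rescue orientation assignment drops parity-conflicting candidate edges
  (possible with near-palindromic sequence) instead of exploring both
  orientations per group.
- Contig `depth` from the external backend is reported as zeros: the ACE
  layout is parsed for membership only.
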