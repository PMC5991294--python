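# Methods

This note records the procedures the package implements, the parameters
that matter, and the design choices made where the behaviour of a dot-plot
post-processor is genuinely underdetermined.

## Match model and coordinates

All alignments are held as PAF-style records: 0-based half-open intervals
on the forward strand of both sequences, a strand flag, the residue-match
count `nmatch` and the alignment block length `blocklen`.  Identity is
always `nmatch / blocklen`; no CIGAR-derived recomputation is attempted,
because the twelve mandatory PAF columns are the only information every
supported aligner provides.  Extra tag columns and the mapping-quality
column are preserved opaquely so that a parse → write round trip is
byte-identical.  MAF pairwise blocks are converted at parse time: the first
`s`-line is the target, the second the query (the pairwise-aligner
convention); `nmatch` counts identical non-gap column pairs
(case-insensitive) and minus-strand coordinates are rewritten to forward
coordinates (`start_fwd = srcSize − start − size`), so downstream code sees
a single convention.  The final strand is reverse iff exactly one of the
two `s`-lines is minus.

## Chunking and stitching

Query sequences longer than `chunk_size` (default 10 Mb, chosen to bound
aligner memory at chromosome scale) are split into `⌈L / chunk_size⌉`
pieces named `<name>_###_<i>`; the separator is rejected in input names so
the original name is always recoverable.  Sequences that fit in one chunk
keep their name and never enter the chunk map, which keeps the common case
(contig-scale assemblies) untouched.  `unchunk` restores names, lengths and
offsets with integer arithmetic and is therefore exact and idempotent.

The chunk map is serialized as a TSV with four columns (chunk name,
original name, offset, original length); the original length is carried
because it cannot be reconstructed from offsets alone when the last chunk
of a sequence produced no alignments.

`merge_contiguous` rejoins alignments that continue each other across
chunk boundaries: same query, target and strand, and both axis gaps within
`gap_tolerance` (default 0 — exact boundary contiguity; real aligner output
is ragged at boundaries, so the CLI exposes the tolerance).  On the reverse
strand the target continuation runs in decreasing coordinates.  Merged
records sum `nmatch` and `blocklen`, so identity is recomputed from totals
rather than averaged and the `identity = nmatch/blocklen` invariant is
preserved.

`project_to_chunks` (the inverse view, used to express whole-sequence
alignments in chunk coordinates) slices a match at chunk boundaries,
apportioning `blocklen` and the target span proportionally with the
remainder on the last piece, and distributing `nmatch` under the per-piece
`nmatch ≤ blocklen` constraint so that totals are exact and a subsequent
unchunk + merge reproduces the original record bit for bit.

## Identity classes and the cap

The four similarity classes (< 25 %, 25–50 %, 50–75 %, ≥ 75 %) are
half-open with each boundary assigned to the upper class; prose ranges are
ambiguous at the exact boundary and this is the convention that keeps the
partition exact on a grid.  To bound drawing cost only the 100 000 largest
alignments are plotted, "largest" meaning greatest `blocklen`, with ties
broken by input order (stable), so the cap is idempotent.

## Axis layout

Each axis concatenates its catalog in order.  Runs of at least two
successive sequences, each shorter than `merge_fraction` (default 0.2 %) of
that axis's total length, are merged into one grayed super-sequence group;
a lone small sequence stays a singleton because there is nothing to merge
it with.  The threshold is evaluated per axis.  Group offsets are strictly
increasing and lengths sum to the axis total.

## Noise filter

Matches are binned by `blocklen` into `⌊N/10⌋` equal-width bins over
`[min, max]`.  The modal bin is the first bin of maximal count scanning in
increasing size order; from the next bin upward, the first bin with count
≤ 1 % of the modal count is the cutoff; matches in bins strictly below the
cutoff are removed.  With fewer than 20 matches, a degenerate size range,
or no bin reaching the 1 % criterion, nothing is removed.  The ≤ comparison
and the plain upward scan (no wrapping) are the simplest readings of the
procedure; the tie-break "first maximal bin" follows from the scan
direction.  Re-running the filter on its own output recomputes the bins and
may remove more; only the non-increasing-count property is guaranteed.

## Sorting and orientation

For each query, the assigned reference is the one maximizing summed
`blocklen` over the query's matches (ties to the earlier catalog entry);
orientation is reverse iff reverse-strand matches to the assigned reference
carry strictly more aligned bases than forward ones (ties stay forward, for
determinism); the position key is the `blocklen`-weighted mean of
target-interval midpoints.  Queries sort by (reference catalog index,
position); unaligned queries follow in their original relative order.
Weighting by matched bases rather than match count makes the result
invariant to how an aligner fragments a long alignment.  Applying the plan
mirrors reversed queries (`qstart' = qlen − qend`, strand toggled), which
is an involution, so unsort restores the plot exactly.

## Summary profile

The reference identity profile is computed on a working copy — the
displayed plot is never modified — in four steps: sort the query along the
reference; drop matches whose reference interval is contained in another
match's interval on the same reference sequence (equal intervals keep the
highest identity, first on tie; containment is judged on the reference axis
only, since the statistic is a reference projection); noise-filter with the
defaults above; then count every reference base once at the highest
identity class covering it.  Counting is integer interval arithmetic with a
single division by the total reference length at the end, so class
fractions plus the uncovered fraction sum to 1 to machine precision.
Max-class-per-base is the only overlap resolution that both avoids double
counting and keeps every fraction ≤ 1.

## Rendering

SVG output is plain SVG 1.1 built element by element: one `line` per
visible match (after active filters and the cap), colored by class from one
of six palettes (including a deuteranopia-safe one); grid lines at sequence
borders; margin labels with middle-ellipsis truncation, grayed over
super-sequences.  PNG output draws the identical scene with Pillow, which
makes byte-for-byte determinism for fixed inputs straightforward to
guarantee.  Matches shorter than `min_visual_length` pixels (default 1) are
padded around their midpoint to stay visible; the strong-precision mode
disables the padding so sub-pixel matches vanish from the picture — it is a
rendering choice, and never deletes matches from the model.

## Synthetic fixtures

The generator plants known structure so every stage is testable without an
aligner: a reference of `n_fragments` random ACGT fragments (defaults: 12
fragments of 50 kb at 95 % identity — a realistic contig-scale assembly
comparison), a query of those fragments permuted, a random subset
reverse-complemented, and point substitutions applied at rate
`1 − identity`.  Substitution-only mutation keeps ground-truth coordinates
exact, which is what the round-trip and recovery tests need; indels,
duplications and rearrangement breakpoints inside fragments are not
modelled, so passing tests demonstrate coordinate and bookkeeping
correctness, not robustness to every signature of real evolution.  Mutation
counts are binomial, so planted identity is reproducible within the usual
3σ band.  A lightweight variant generates catalogs plus consistent matches
without residues for chromosome-scale chunking tests.  The external-aligner
wrapper shells out to minimap2 (or any tool declared in a `tools.yaml` with
executable, command skeleton, threads and an advisory memory cap) with its
default parameters; the aligner is never reimplemented.

## Problem sizes and numerics

The test and acceptance workloads use 1–30 Mb synthetic catalogs for
chunking (coordinates only; residues are only materialized at the tens-of-
kilobase scale where the external aligner is involved), match sets of 20–
5000 for the noise filter, references ≤ 10 kb for the per-base summary
oracle, and 8–40 fragments for sort recovery — sizes at which the
brute-force oracles remain exact and fast while exercising every code
path, including multi-chunk splits.  All coordinate arithmetic is integer;
the only floating-point quantities are identities, layout scaling and the
final profile fractions.

## Known limitations

- Only the query axis is chunked and sorted; the reference order is always
  the catalog order.
- The noise filter's equal-width binning is sensitive to a single extreme
  `blocklen` outlier, which compresses all small matches into one bin; this
  mirrors the histogram definition rather than attempting robustness.
- `remove_included` is quadratic-free (sort + sweep) but the per-base class
  resolution in the summary is O(breakpoints × matches) per reference
  sequence, which is fine for post-filter match counts but not for millions
  of overlapping records.
- The backup archive layout (tar.gz with members `query.fasta`,
  `target.fasta`, `alignment.paf`, optionally gzip-compressed FASTA) is
  this tool's own dialect.
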