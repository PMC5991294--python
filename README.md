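# dotplot

Static genome-to-genome dot plots from pairwise whole-genome alignments.

`dotplot` is a headless library and command-line tool for comparing two
(possibly multi-sequence, chromosome-scale) nucleic sequence sets.  It
ingests alignments in PAF or MAF format together with the two sequence
catalogs (FASTA, gzip FASTA, or `.fai` index), applies the standard
post-processing a dot-plot viewer needs — chunk stitching, noise filtering,
query ordering and orientation, identity summarization — and writes
publication-ready SVG/PNG plots plus table and sequence exports.  It is
aimed at assembly assessment: spotting inversions, translocations, breaks
and repeats between an assembly and a reference, and quantifying how much
of the reference is covered at which similarity level.

## The model

A match is one local alignment record `(q, qstart, qend, strand, t, tstart,
tend, nmatch, blocklen)` in 0-based half-open coordinates; its **identity**
is `nmatch / blocklen` (PAF columns 10/11), binned into four classes:
< 25 %, 25–50 %, 50–75 %, ≥ 75 %.  The main procedures:

- **Chunking** — query sequences longer than 10 Mb are split into 10 Mb
  chunks before alignment (bounding aligner memory); afterwards chunk
  coordinates are shifted back exactly and alignments that continue each
  other across chunk boundaries are rejoined, summing `nmatch` and
  `blocklen`.
- **Noise filter** — matches are binned by block length into ⌊N/10⌋
  equal-width bins; the first bin of maximal count (scanning small→large)
  is the mode, the first later bin whose count falls to 1 % of the modal
  count is the cutoff, and every match in bins below the cutoff is noise.
- **Sort/orient** — each query contig is assigned to the reference
  sequence carrying the most aligned bases, flipped when the majority of
  those bases are on the reverse strand, and placed at the
  block-length-weighted mean midpoint of its matches, maximizing the
  visual diagonal.
- **Summary profile** — after sorting, dropping matches whose reference
  interval is contained in another's, and noise filtering, each reference
  base is counted once at the highest identity class covering it; the
  profile reports per-class fractions of the total reference length plus
  the uncovered fraction.
- **Rendering** — only the 100 000 largest alignments are drawn; runs of
  successive sequences smaller than 0.2 % of an axis merge into a grayed
  super-sequence; sub-pixel matches are padded to stay visible unless
  strong precision is requested.

## Worked example

Simulate a rearranged genome pair with exact ground truth, then plot it:

```bash
dotplot simulate --seed 7 --fragments 6 --fragment-length 5000 --identity 0.92 -o sim
# {"reference": "sim/reference.fasta", "query": "sim/query.fasta", "truth": "sim/truth.paf",
#  "permutation": [0, 3, 5, 2, 1, 4], "reversed": [0, 1, 2, 3, 4]}

dotplot plot sim/truth.paf --query-meta sim/query.fasta \
        --target-meta sim/reference.fasta -o out --sort
cat out/summary.tsv
# class   percent
# <25%    0
# 25-50%  0
# 50-75%  0
# >75%    100
# no match        0
```

The 30 kb reference is fully covered at ≥ 75 % identity (the planted
fragments are 92 % identical to their sources), so the whole profile sits
in the top class.  `out/` also contains `dotplot.svg`/`dotplot.png` (the
plot, with the six fragments forming a clean diagonal after sorting),
`association.tsv` (each query's assigned reference) and `alignment.paf`.
With minimap2 installed the same pair can be aligned from scratch:

```bash
dotplot align sim/reference.fasta sim/query.fasta -o aligned --sort
```

which chunks the query, runs the aligner, stitches boundary alignments and
writes the same artifact set.

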