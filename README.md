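# rangekit

Infrastructure for computing on annotated genomic ranges in Python: a range
vector type with a complete interval algebra, an interval-index overlap
engine, run-length-encoded genome-scale vectors with coverage and Views,
strand-aware genomic ranges and grouped range lists, CIGAR-aware alignment
decomposition, a transcript-model store with exon/transcript/gene queries,
and multi-sample overlap counting — plus a `rangekit` CLI for shell use.

It is aimed at anyone doing range-based genomics — annotating ChIP-seq peaks,
counting RNA-seq reads over transcripts, intersecting variant positions with
gene models — who wants these operations as composable in-memory data
structures rather than chains of file-format conversions.

## The model

A *range* is an ordered set of consecutive integer positions, stored 1-based
and closed as `(start, end)` with `width = end − start + 1`; `end = start − 1`
encodes a legal zero-width range (an insertion point). On top of
`IntegerRanges` sit:

- **the interval algebra** — `shift`, `resize`, `flank`, `restrict`,
  `distance`, `reduce` (merge overlapping *and adjacent* ranges), `disjoin`
  (split at every endpoint so each piece has a constant covering set),
  `gaps` (bounded complement), set and parallel-set operations — all treating
  a range vector as a set of integer positions;
- **overlap detection** — subjects are indexed once (sorted starts + a
  max-end segment tree) for `O(log n + hits)` window queries in modes
  `any`/`within`/`equal` with `max_gap`/`min_overlap` refinements, plus
  `nearest`/`precede`/`follow`;
- **coverage** — per-position counts stored as run-length-encoded
  `RleVector`s computed event-wise (chromosome-scale domains never
  materialize), with `which_max`, window extraction, `slice_above` for
  threshold peaks, and `Views` summaries (`view_sums`, `view_maxs`);
- **genomic semantics** — `GenomicRanges` adds sequence name, strand and a
  `SeqInfo` registry (names, lengths, genome build; mixed-build operations
  error). `resize`/`flank` anchor on the 5′ end, so "start" means the
  rightmost coordinate on the `−` strand. `GenomicRangesList` stores compound
  features (exons-by-transcript, gapped reads) as one flat vector plus a
  partition; list overlap reports one hit per element pair;
- **alignments and gene models** — CIGARs decompose into reference-space
  segments (`M/=/X/D` extend, `N` splits, `I/S/H/P` consume nothing);
  GTF/GFF3 gene models load into a relational `TranscriptStore` (SQLite
  persistence) queried by `exons`, `exons_by`, `transcripts`, `genes`;
- **counting** — `count_features` and `summarize_overlaps` produce a
  `SummarizedExperiment` (assays × row ranges × sample table), optionally
  discarding reads that hit more than one feature.

## Worked example

The bundled fixtures reproduce the KRAS isoform-A gene model and three CTCF
ChIP-seq reads:

```python
import rangekit as rk
from rangekit.fixtures import kras_fixture, ctcf_fixture

store, by_tx = kras_fixture()
kras_a = by_tx["48666"]
print(len(kras_a), kras_a.starts[0], kras_a.ends[0])
# 5 106118565 106118681

reads = ctcf_fixture()                      # 3 reads, 24 nt each, chr10 '+'
frags = rk.genomic_resize(reads, 120, "start")   # extend to fragment size
cov = rk.genomic_coverage(frags)["chr10"]
print(int(cov.sum()), rk.which_max(cov))
# 360 3012944
```

Transcript `48666` has five exons, the first spanning
106,118,565–106,118,681 (width 117). Extending the three 24 nt reads to
120 nt fragments (starts fixed — they are all on `+`) gives a coverage
vector of total mass 3 × 120 = 360 whose maximum is first reached at
position 3,012,944, where all three fragments stack.

The same flows are available from the shell, e.g.
`rangekit fixtures export ctcf -o ctcf.bed && rangekit coverage ctcf.bed -o cov.bg`.

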