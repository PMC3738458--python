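# Methods

## Coordinate model

All ranges are 1-based, closed intervals; `width = end − start + 1`. This is
the convention used by GFF and by the genome browsers the bundled gene-model
fixture was derived from, so exon endpoints are stored verbatim. The
zero-width range `end = start − 1` is legal throughout: it models an
insertion point (a BED feature with `start == end`), makes `flank(r, 0)` and
`p_gap` of adjacent ranges total, and by construction can never produce an
overlap hit (its overlap width with anything is ≤ 0) nor contribute to
coverage. All conversions to and from 0-based half-open coordinates (BED,
bedGraph) happen in `rangekit.io` and nowhere else; no other module performs
basis arithmetic.

## The interval algebra

`reduce` merges overlapping **and adjacent** ranges at its default
`min_gap = 0`; `min_gap = k` additionally merges ranges separated by ≤ k
positions. Zero-width inputs cover no positions and are dropped (they are
reported as `-1` in the returned index map so callers can still account for
them). `disjoin` cuts the covered positions at every input start and every
`end + 1`, keeping pieces covered by at least one input; each piece's
covering-input set is constant along its extent and is returned alongside.
Set operations (`set_union`, `set_intersect`, `set_setdiff`, `gaps`) are
defined on the covered-position sets of their arguments and always return
reduced range vectors.

Choices that were genuinely open, and how they were fixed:

- **`resize(anchor="center")` tie-break**: `new_start = start +
  floor((old_width − new_width) / 2)`; an odd width change puts the extra
  base on the right. Deterministic and order-preserving; the midpoint moves
  by at most half a position.
- **`p_setdiff` that would split a range errors** (naming the offending
  index) rather than guessing: a single range cannot represent two pieces.
  Callers wanting fragments use `set_setdiff` per element.
- **`distance` counts positions strictly between** its arguments, so
  overlapping *and adjacent* pairs are at distance 0.
- **`split_ranges`/`group_genomic` order groups by first appearance** of
  each factor level, which keeps grouping stable without imposing a
  collation order on opaque identifiers.
- **Annotation columns ride along row-wise** through extraction, sorting and
  splitting. `reduce`/`disjoin` drop annotations and return index maps
  instead: merging rows has no canonical semantics (sum? first? concat?), so
  re-aggregation is left to the caller, losslessly.

## Overlap engine

The subject vector is indexed once: ranges sorted by start, plus a perfect
binary segment tree over the ends supporting range-maximum queries. A window
query for "start ≤ hi and end ≥ lo" binary-searches the start array for the
prefix and then descends only tree nodes whose max end clears `lo`, giving
O(n log n) construction and O(log n + hits) enumeration; batch queries walk
the same structure. The index keeps a SHA-1 fingerprint of the indexed
coordinates and re-checks it on every query, so an index whose subject was
mutated after construction raises instead of silently answering for stale
data.

Hit semantics: `any` requires overlap width ≥ `min_overlap`, or, when
`max_gap > 0`, separation ≤ `max_gap`; `within` requires the query to be a
subregion of the subject; `equal` requires identical endpoints. `max_gap`
applies only to mode `any` (its meaning under containment/equality is not
well defined); `min_overlap` applies to every mode, which is what makes
zero-width ranges hit-free at the defaults. Adjacency is not overlap at the
defaults. Hits are returned sorted by (query index, subject index) so
downstream joins are reproducible. `nearest` breaks ties toward the lowest
subject index (an `all_ties` option returns every co-minimal subject);
`precede`/`follow` return a `-1` sentinel when no neighbour exists on the
required side. The neighbour queries use a vectorized all-pairs scan rather
than the tree: at the scales where neighbour queries are used here the scan
is dominated by constant factors, and the brute-force oracle equivalence is
what the tests enforce.

## RLE vectors and coverage

`RleVector` stores (value, run-length) pairs in canonical form — no
zero-length runs, no equal adjacent values — so the encoding of a vector is
unique and `encode(decode(x)) == x`. Coverage is computed from sorted
endpoint events (`+1` at each start, `−1` past each end), never by
materializing a per-position array, so chromosome-sized domains cost
O(n log n) in the number of ranges. Ranges extending beyond the domain are
clipped before counting, matching the view that fragment extension may
legitimately overhang contig ends; `trim` is available when hard clipping of
the ranges themselves is wanted, and `out_of_bounds()` exposes the mask.

`which_max` returns the first position attaining the maximum (reproducible
peak-finding). `slice_above` uses a closed threshold (`value ≥ lower`), with
a `strict` option; the resulting `Views` bind the peak ranges to the
original vector. `view_maxs` of a zero-width view errors by default — the
maximum over an empty set has no identity — with an `empty_sentinel` escape
hatch; `view_sums` of a zero-width view is 0.

## Genomic semantics

Strand `*` matches any strand in overlap detection and behaves as `+` in
`resize`/`flank`. On the `−` strand, "start" is the rightmost coordinate
(the 5′ end), so `genomic_flank(side="start")` is always the upstream,
promoter-side flank. Operations across differing non-empty genome-build tags
raise; `SeqInfo` preserves insertion order of sequence names but compares by
name identity. `GenomicRangesList` stores one flat `GenomicRanges` plus a
partition; element-level overlap deduplicates multiple member-range hits to
one hit per (query element, subject element) pair, the semantics needed for
counting. `keep_seqlevels` on a list drops member ranges but keeps (possibly
empty) groups so feature keys remain stable.

## Alignments

CIGAR decomposition follows the SAM reference-consumption rules: `M`, `=`,
`X` and `D` extend the current reference segment (adjacent matches and
deletions merge — no zero-length gaps), `N` closes the segment and opens a
new one after the skip, `I`/`S`/`H`/`P` consume nothing. Zero-length ops are
rejected at parse time with the character offset; a CIGAR consuming no
reference positions is an error, not a silent drop. SAM text is read via
pysam (header `@SQ` lines populate the `SeqInfo`); unmapped records are
skipped, strand derives from flag bit 16, and secondary/supplementary
records are kept unless `primary_only` is set — filtering policy is the
caller's, not the reader's. Paired-end pairing is out of scope.

## Gene models

The store is relational: an exon table (exons deduplicated by coordinates
and strand, shared between transcripts), a transcript table, and a splicing
table with per-transcript exon ranks. Ranks run 1..k, ascending with genomic
position on `+` transcripts and descending on `−` (rank 1 is the 5′-most
exon); when the input lacks a rank attribute, ranks are assigned from
(start, end) lexicographic order within the strand orientation — an
assumption for identical-start exons, recorded here. GTF
`gene_id`/`transcript_id` attributes are authoritative; GFF3 resolves
exon → mRNA → gene through Parent/ID with exactly one level of indirection.
A transcript whose exons span multiple sequences or strands is rejected by
name. Ingest is line-order invariant. Persistence is a single-file SQLite
database with an embedded `schema_version` row checked on load; identifiers
are opaque text throughout (no symbol lookup).

## Counting

"Overlap" for counting means element-level mode `any` at defaults, with
`min_overlap` available for conservative exon counting. The
`union_discard_multihit` mode first deduplicates hits to one per
(feature, read) pair — so a spliced read touching two exons of one
transcript is *not* a multi-hit — then discards reads hitting more than one
feature; consequently each column of the counts matrix sums to at most the
sample's read count. The library default is `ignore_strand=False`; the CLI
`count` verb defaults to `ignore_strand=True`, the usual unstranded RNA-seq
recipe. Assays are dense integer matrices.

## Synthetic data and what the tests show

The generator draws range sets with defaults emulating a small
ChIP-seq-like workload: 2 contigs of 10 kb, 200 ranges of 20–50 nt
(read-sized), strands 45/45/10% `+`/`−`/`*`, 1–4 ranges per compound
feature, and spliced CIGARs of up to 3 segments with skips up to 200 nt.
Ground truth (dense per-position coverage, all-pairs overlap sets) is
computed by `rangekit.naive` — plain-Python per-position loops and
all-pairs scans sharing no code with the optimized modules — so generated
data double as genuine oracles. The oracle suites run 100 seeded instances
of 20–150 ranges with coordinates up to 10⁵ and widths up to 300,
exercising all overlap modes, reduce/disjoin, set operations, coverage,
peak slicing and nearest neighbours; instance sizes were chosen so the
brute-force side stays honest while the whole suite completes in seconds.
What these tests do *not* show: behaviour on real read data with quality
artefacts, duplicated fragments, or realistic fragment-length
distributions — the generator makes no attempt at error profiles, and
paired-end structure is out of scope.

## Known limitations

No circular chromosomes; no nucleotide-sequence storage (annotation columns
accept opaque payloads); no BAM/bigWig binary formats (SAM text and
bedGraph only); no VCF; only `any`/`within`/`equal` overlap modes are
exposed (not the full interval-relation algebra); no normalization or
differential-expression statistics downstream of the counts matrix.
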