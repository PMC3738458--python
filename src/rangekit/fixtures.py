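"""Bundled worked-example data and a seeded synthetic generator.

Three small data sets ship with the package so that every module is testable
without downloads:

* the five exons of KRAS isoform A (transcript ``48666``) as a GTF gene
  model — note the upstream annotation prints these on ``chr13``, which this
  package reproduces verbatim rather than correcting;
* the first three CTCF ChIP-seq read alignments on mouse chr10 (mm9),
  24 nt effective read length;
* an eight-row excerpt of per-site variant tallies from a human (hg19)
  CTCF ChIP-seq sample.

:func:`generate` draws reproducible random range sets from a
:class:`SyntheticSpec` and attaches ground truth computed by the naive
brute-force reference path (:mod:`rangekit.naive`), so generated data double
as oracle tests for the optimized modules.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np

from .core import AnnotationTable, IntegerRanges
from .genemodels import TranscriptStore, exons_by, store_from_gff
from .genomic import GenomicRanges, GenomicRangesList, SeqInfo, group_genomic
from . import naive

__all__ = [
    "KRAS_GTF",
    "kras_fixture",
    "ctcf_fixture",
    "variant_excerpt_fixture",
    "ctcf_sam_fixture",
    "SyntheticSpec",
    "generate",
    "mm9_seqinfo",
    "hg19_seqinfo",
    "saccer2_seqinfo",
]

# SeqInfo stubs: names and lengths for only the chromosomes the fixtures touch


def mm9_seqinfo() -> SeqInfo:
    return SeqInfo(["chr10", "chr11", "chr12"],
                   {"chr10": 129993255, "chr11": 121843856,
                    "chr12": 121257530},
                   genome="mm9")


def hg19_seqinfo() -> SeqInfo:
    return SeqInfo(["chr1", "chr13"],
                   {"chr1": 249250621, "chr13": 115169878},
                   genome="hg19")


def saccer2_seqinfo() -> SeqInfo:
    return SeqInfo(["chrXIII"], {"chrXIII": 924431}, genome="sacCer2")


# KRAS isoform A: 5 exons of transcript 48666 (gene 3845), printed on chr13.
KRAS_GTF = """\
chr13\tknownGene\texon\t106118565\t106118681\t.\t+\t.\tgene_id "3845"; transcript_id "48666"; exon_id "174810"; exon_rank "1";
chr13\tknownGene\texon\t106119356\t106119490\t.\t+\t.\tgene_id "3845"; transcript_id "48666"; exon_id "174811"; exon_rank "2";
chr13\tknownGene\texon\t106124887\t106125034\t.\t+\t.\tgene_id "3845"; transcript_id "48666"; exon_id "174814"; exon_rank "3";
chr13\tknownGene\texon\t106142141\t106142541\t.\t+\t.\tgene_id "3845"; transcript_id "48666"; exon_id "174818"; exon_rank "4";
chr13\tknownGene\texon\t106143261\t106143383\t.\t+\t.\tgene_id "3845"; transcript_id "48666"; exon_id "174820"; exon_rank "5";
"""


def kras_fixture() -> tuple[TranscriptStore, GenomicRangesList]:
    """The KRAS gene-model fixture: store + exons grouped by transcript."""
    store = store_from_gff(_io.StringIO(KRAS_GTF), dialect="gtf",
                           seq_info=hg19_seqinfo(),
                           metadata={"source": "bundled KRAS fixture"})
    return store, exons_by(store, group="transcript")


def ctcf_fixture() -> GenomicRanges:
    """Three CTCF ChIP-seq read alignments on mm9 chr10 (24 nt each)."""
    ranges = IntegerRanges([3012936, 3012941, 3012944],
                           [3012959, 3012964, 3012967])
    return GenomicRanges(["chr10"] * 3, ranges, ["+"] * 3, mm9_seqinfo())


def ctcf_sam_fixture() -> str:
    """The CTCF reads as minimal single-end SAM text (24M CIGARs)."""
    si = mm9_seqinfo()
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for n in si.seq_names:
        lines.append(f"@SQ\tSN:{n}\tLN:{si.seq_lengths[n]}")
    g = ctcf_fixture()
    for i in range(len(g)):
        lines.append("\t".join([
            f"ctcf_read{i + 1}", "0", str(g.seq_names[i]), str(g.starts[i]),
            "255", "24M", "*", "0", "0", "*", "*"]))
    return "\n".join(lines) + "\n"


_VARIANT_ROWS = [
    # (pos, ref, alt, ncycles, count, count_ref)
    (11391, "T", "A", 7, 19, 5),
    (793522, "T", "A", 1, 4, 10),
    (825860, "G", "A", 1, 4, 5),
    (968600, "A", "C", 2, 5, 6),
    (1057713, "A", "C", 3, 4, 19),
    (1376423, "G", "C", 5, 5, 53),
    (1376430, "T", "C", 4, 4, 51),
    (1610542, "A", "C", 4, 4, 28),
]


def variant_excerpt_fixture() -> GenomicRanges:
    """Eight single-position variant-tally sites on hg19 chr1 with
    ref/alt/ncycles/count/count.ref annotations."""
    pos = [r[0] for r in _VARIANT_ROWS]
    ann = AnnotationTable({
        "ref": [r[1] for r in _VARIANT_ROWS],
        "alt": [r[2] for r in _VARIANT_ROWS],
        "ncycles": [r[3] for r in _VARIANT_ROWS],
        "count": [r[4] for r in _VARIANT_ROWS],
        "count.ref": [r[5] for r in _VARIANT_ROWS],
    })
    ranges = IntegerRanges(pos, pos, annotations=ann)
    return GenomicRanges(["chr1"] * len(pos), ranges,
                         ["+"] * len(pos), hg19_seqinfo())


# -- synthetic data ------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a reproducible random range set.

    Defaults emulate a small ChIP-seq-like workload: a couple of short
    contigs, reads of 20-50 nt, mostly stranded, grouped a few ranges per
    compound feature when a list is requested.
    """

    seed: int = 0
    n_sequences: int = 2
    sequence_length: int = 10_000
    n_ranges: int = 200
    width_min: int = 20
    width_max: int = 50
    strand_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)  # + - *
    ranges_per_group: tuple[int, int] = (1, 4)
    cigar_max_segments: int = 3
    cigar_gap_max: int = 200


@dataclass
class GeneratedRanges:
    """A synthetic GenomicRanges with brute-force ground truth attached."""

    granges: GenomicRanges
    coverage_truth: dict[str, list[int]]       # dense per-position counts
    self_overlap_truth: dict[str, list[tuple[int, int]]]  # per-seq pair lists


def _draw_granges(rng: np.random.Generator, spec: SyntheticSpec) -> GenomicRanges:
    seq_names = [f"seq{i + 1}" for i in range(spec.n_sequences)]
    info = SeqInfo(seq_names, {n: spec.sequence_length for n in seq_names})
    if spec.width_max > spec.sequence_length:
        raise ValueError("width_max exceeds sequence length")
    n = spec.n_ranges
    seqs = rng.integers(0, spec.n_sequences, size=n)
    widths = rng.integers(spec.width_min, spec.width_max + 1, size=n)
    starts = np.array([rng.integers(1, spec.sequence_length - w + 2)
                       for w in widths])
    strands = rng.choice(np.array(["+", "-", "*"], dtype=object), size=n,
                         p=spec.strand_probs)
    return GenomicRanges([seq_names[i] for i in seqs],
                         IntegerRanges(starts, starts + widths - 1),
                         strands, info)


def generate(spec: SyntheticSpec) -> GeneratedRanges:
    """Draw a random GenomicRanges and compute its ground truth naively."""
    rng = np.random.default_rng(spec.seed)
    g = _draw_granges(rng, spec)
    cov_truth: dict[str, list[int]] = {}
    ovl_truth: dict[str, list[tuple[int, int]]] = {}
    for seq in g.seq_info.seq_names:
        idx = np.nonzero(g.seq_names == seq)[0]
        pairs = [(int(g.starts[i]), int(g.ends[i])) for i in idx]
        cov_truth[seq] = naive.naive_coverage(pairs, spec.sequence_length)
        ovl_truth[seq] = naive.naive_find_overlaps(pairs, pairs)
    return GeneratedRanges(g, cov_truth, ovl_truth)


def generate_list(spec: SyntheticSpec) -> GenomicRangesList:
    """Group a synthetic draw into compound features of random size."""
    rng = np.random.default_rng(spec.seed)
    g = _draw_granges(rng, spec)
    lo, hi = spec.ranges_per_group
    factor = []
    gid = 0
    remaining = len(g)
    while remaining > 0:
        k = min(int(rng.integers(lo, hi + 1)), remaining)
        factor.extend([f"g{gid}"] * k)
        gid += 1
        remaining -= k
    return group_genomic(g, factor)


def generate_cigars(spec: SyntheticSpec) -> list[str]:
    """Random valid CIGARs: M segments separated by N gaps, with optional
    soft clips and indels."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_ranges):
        n_seg = int(rng.integers(1, spec.cigar_max_segments + 1))
        parts = []
        if rng.random() < 0.3:
            parts.append(f"{int(rng.integers(1, 10))}S")
        for k in range(n_seg):
            parts.append(f"{int(rng.integers(1, 50))}M")
            if rng.random() < 0.3:
                parts.append(f"{int(rng.integers(1, 5))}"
                             f"{'I' if rng.random() < 0.5 else 'D'}")
                parts.append(f"{int(rng.integers(1, 50))}M")
            if k < n_seg - 1:
                parts.append(f"{int(rng.integers(1, spec.cigar_gap_max + 1))}N")
        if rng.random() < 0.3:
            parts.append(f"{int(rng.integers(1, 10))}S")
        out.append("".join(parts))
    return out
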