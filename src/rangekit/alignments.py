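"""Single-end read alignments and CIGAR decomposition.

A :class:`GappedAlignment` records where one read landed on the reference:
sequence name, 1-based leftmost position, strand, and the CIGAR string
encoding the alignment's structure. On the reference, M/=/X (aligned) and D
(deletion) consume positions within a segment; N (skipped region, typically
an intron) ends the current segment and opens a new one after the skip;
I/S/H/P consume nothing. A spliced read therefore decomposes into one range
per exon-aligned segment, while its *extent* is the single ungapped span.

SAM text is read through pysam; only QNAME, FLAG, RNAME, POS and CIGAR are
used. Unmapped records (flag bit 4) are skipped; strand comes from flag bit
16. Secondary/supplementary alignments are kept by default (``primary_only``
filters them).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pysam

from .core import IntegerRanges, RangesError
from .genomic import GenomicRanges, GenomicRangesList, SeqInfo

__all__ = [
    "GappedAlignment",
    "parse_cigar",
    "reference_width",
    "alignment_to_gapped_ranges",
    "alignment_extent",
    "read_alignments",
]

_CIGAR_OPS = "MIDNSHP=X"
_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("M=XDN")
_SEGMENT_OPS = set("M=XD")


@dataclass(frozen=True)
class GappedAlignment:
    """One aligned read: position + CIGAR on a named reference sequence."""

    seq_name: str
    pos: int
    cigar: str
    strand: str = "*"
    read_name: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise RangesError(f"alignment position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-", "*"):
            raise RangesError(f"invalid strand {self.strand!r}")
        parse_cigar(self.cigar)  # validates


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Tokenize a CIGAR string into (op, length) pairs.

    Raises with the character offset of the first malformed token.
    """
    if not cigar:
        raise RangesError("empty CIGAR string")
    out: list[tuple[str, int]] = []
    offset = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != offset:
            raise RangesError(
                f"malformed CIGAR {cigar!r} at offset {offset}")
        length = int(m.group(1))
        if length == 0:
            raise RangesError(
                f"zero-length CIGAR op {m.group(2)!r} at offset {m.start()}")
        out.append((m.group(2), length))
        offset = m.end()
    if offset != len(cigar):
        raise RangesError(f"malformed CIGAR {cigar!r} at offset {offset}")
    return out


def reference_width(cigar: str) -> int:
    """Reference positions spanned: sum of M/=/X/D/N lengths."""
    return sum(n for op, n in parse_cigar(cigar) if op in _REF_CONSUMING)


def _segments(a: GappedAlignment) -> list[tuple[int, int]]:
    """Reference-space (start, end) segments split at N gaps."""
    segs: list[tuple[int, int]] = []
    cursor = a.pos
    seg_start: int | None = None
    for op, n in parse_cigar(a.cigar):
        if op in _SEGMENT_OPS:
            if seg_start is None:
                seg_start = cursor
            cursor += n
        elif op == "N":
            if seg_start is not None:
                segs.append((seg_start, cursor - 1))
                seg_start = None
            cursor += n
        # I/S/H/P consume no reference
    if seg_start is not None:
        segs.append((seg_start, cursor - 1))
    if not segs:
        raise RangesError(
            f"CIGAR {a.cigar!r} consumes no reference positions")
    return segs


def alignment_to_gapped_ranges(a: GappedAlignment,
                               seq_info: SeqInfo | None = None) -> GenomicRanges:
    """The aligned reference segments of one read (one range per segment)."""
    segs = _segments(a)
    n = len(segs)
    return GenomicRanges(
        np.full(n, a.seq_name, dtype=object),
        IntegerRanges([s for s, _ in segs], [e for _, e in segs]),
        np.full(n, a.strand, dtype=object),
        seq_info)


def alignment_extent(a: GappedAlignment,
                     seq_info: SeqInfo | None = None) -> GenomicRanges:
    """The single ungapped span [pos, pos + reference_width - 1]."""
    w = reference_width(a.cigar)
    if w == 0:
        raise RangesError(f"CIGAR {a.cigar!r} consumes no reference positions")
    return GenomicRanges([a.seq_name],
                         IntegerRanges([a.pos], [a.pos + w - 1]),
                         [a.strand], seq_info)


def read_alignments(sam_path, primary_only: bool = False):
    """Load single-end alignments from SAM text.

    Returns ``(alignments, gapped, seq_info)``: the retained
    :class:`GappedAlignment` records, a :class:`GenomicRangesList` with one
    element per record holding its gapped reference ranges, and the
    :class:`SeqInfo` built from the @SQ header lines.
    """
    alns: list[GappedAlignment] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        names = list(fh.references)
        lengths = {n: int(L) for n, L in zip(fh.references, fh.lengths) if L}
        seq_info = SeqInfo(names, lengths)
        for rec in fh:
            if rec.is_unmapped:
                continue
            if primary_only and (rec.is_secondary or rec.is_supplementary):
                continue
            if rec.reference_name is None or not rec.cigarstring:
                continue
            alns.append(GappedAlignment(
                seq_name=rec.reference_name,
                pos=rec.reference_start + 1,  # pysam is 0-based
                cigar=rec.cigarstring,
                strand="-" if rec.is_reverse else "+",
                read_name=rec.query_name))
    gapped = alignments_to_list(alns, seq_info)
    return alns, gapped, seq_info


def alignments_to_list(alns: list[GappedAlignment],
                       seq_info: SeqInfo | None = None) -> GenomicRangesList:
    """One list element per alignment, holding its gapped ranges."""
    starts: list[int] = []
    ends: list[int] = []
    seqs: list[str] = []
    strands: list[str] = []
    sizes: list[int] = []
    names: list[str] = []
    for i, a in enumerate(alns):
        segs = _segments(a)
        sizes.append(len(segs))
        names.append(a.read_name or f"read{i}")
        for s, e in segs:
            starts.append(s)
            ends.append(e)
            seqs.append(a.seq_name)
            strands.append(a.strand)
    if seq_info is None:
        seq_info = SeqInfo(list(dict.fromkeys(seqs)))
    flat = GenomicRanges(np.asarray(seqs, dtype=object),
                         IntegerRanges(starts, ends),
                         np.asarray(strands, dtype=object), seq_info)
    return GenomicRangesList(flat, sizes, names=names)
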