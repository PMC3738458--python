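"""Genome-aware ranges: sequence registry, strand semantics, grouped lists.

A :class:`GenomicRanges` is an :class:`~rangekit.core.IntegerRanges` plus a
sequence (chromosome) name and strand per range, and a :class:`SeqInfo`
registry carrying the chromosome set, optional lengths, and genome build tag.
Tracking the build guards against silently mixing coordinates across
assemblies: operations between ranges with differing, non-empty build tags
raise.

Strand semantics: ``+`` and ``*`` anchor on the leftmost coordinate, ``-``
mirrors — "start" means the 5' end in transcription direction. ``*`` matches
any strand in overlap detection; ``+`` and ``-`` are incompatible unless
``ignore_strand`` is set.

A :class:`GenomicRangesList` groups ranges into compound features
(exons-by-transcript, gapped reads). Internally there is only a single flat
GenomicRanges plus a partition; overlap between lists is reported at the
element (group) level: one hit per (query element, subject element) pair if
any member ranges overlap.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import core
from .core import AnnotationTable, IntegerRanges, RangesError, RangesGrouping
from .overlap import Hits, find_overlaps
from .rle import RleVector, coverage

__all__ = [
    "SeqInfo",
    "GenomicRanges",
    "GenomicRangesList",
    "genomic_resize",
    "genomic_flank",
    "genomic_find_overlaps",
    "keep_seqlevels",
    "rename_seqlevels",
    "group_genomic",
    "list_extract",
    "genomic_coverage",
    "flip_strand",
    "trim",
]

_STRANDS = ("+", "-", "*")


class SeqInfo:
    """Registry of sequence names with optional lengths and genome build."""

    def __init__(self, seq_names: Sequence[str],
                 seq_lengths: Mapping[str, int] | Sequence[int] | None = None,
                 genome: str | None = None):
        names = [str(n) for n in seq_names]
        if len(set(names)) != len(names):
            raise RangesError("sequence names must be unique")
        self.seq_names = names
        if seq_lengths is None:
            self.seq_lengths: dict[str, int | None] = {n: None for n in names}
        elif isinstance(seq_lengths, Mapping):
            unknown = set(seq_lengths) - set(names)
            if unknown:
                raise RangesError(f"lengths for unknown sequences: {sorted(unknown)}")
            self.seq_lengths = {n: seq_lengths.get(n) for n in names}
        else:
            if len(seq_lengths) != len(names):
                raise RangesError("seq_lengths length mismatch")
            self.seq_lengths = dict(zip(names, (int(x) for x in seq_lengths)))
        for n, L in self.seq_lengths.items():
            if L is not None and int(L) <= 0:
                raise RangesError(f"sequence {n!r} has non-positive length")
        self.genome = genome

    def length_of(self, name: str) -> int | None:
        if name not in self.seq_lengths:
            raise KeyError(f"unknown sequence {name!r}")
        return self.seq_lengths[name]

    def subset(self, names: Sequence[str]) -> "SeqInfo":
        missing = [n for n in names if n not in self.seq_lengths]
        if missing:
            raise RangesError(f"unknown sequence levels: {missing}")
        return SeqInfo(list(names),
                       {n: self.seq_lengths[n] for n in names},
                       genome=self.genome)

    def rename(self, mapping: Mapping[str, str]) -> "SeqInfo":
        missing = [n for n in mapping if n not in self.seq_lengths]
        if missing:
            raise RangesError(f"unknown sequence levels: {missing}")
        new_names = [mapping.get(n, n) for n in self.seq_names]
        return SeqInfo(new_names,
                       {mapping.get(n, n): L for n, L in self.seq_lengths.items()},
                       genome=self.genome)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SeqInfo):
            return NotImplemented
        return (self.seq_names == other.seq_names
                and self.seq_lengths == other.seq_lengths
                and self.genome == other.genome)

    def __repr__(self) -> str:
        g = f", genome={self.genome!r}" if self.genome else ""
        return f"SeqInfo({len(self.seq_names)} sequences{g})"


def _check_same_build(a: SeqInfo, b: SeqInfo, op: str):
    if a.genome and b.genome and a.genome != b.genome:
        raise RangesError(
            f"{op} across genome builds ({a.genome!r} vs {b.genome!r}); "
            "lift over or clear the build tag first")


class GenomicRanges:
    """Ranges located on named sequences with a strand designation."""

    def __init__(self, seq_names, ranges: IntegerRanges, strand=None,
                 seq_info: SeqInfo | None = None):
        seq_names = np.asarray([str(s) for s in seq_names], dtype=object)
        if len(seq_names) != len(ranges):
            raise RangesError("seq_names length mismatch")
        if strand is None:
            strand = np.full(len(ranges), "*", dtype=object)
        else:
            strand = np.asarray([str(s) for s in strand], dtype=object)
            if len(strand) != len(ranges):
                raise RangesError("strand length mismatch")
            bad = [s for s in np.unique(strand) if s not in _STRANDS]
            if bad:
                raise RangesError(f"invalid strand value(s) {bad}; use + - *")
        if seq_info is None:
            seen = list(dict.fromkeys(seq_names.tolist()))
            seq_info = SeqInfo(seen)
        else:
            unknown = set(seq_names.tolist()) - set(seq_info.seq_names)
            if unknown:
                raise RangesError(
                    f"ranges on sequences absent from SeqInfo: {sorted(unknown)}")
        self.seq_names = seq_names
        self.ranges = ranges
        self.strand = strand
        self.seq_info = seq_info

    # delegation ------------------------------------------------------------

    @property
    def starts(self) -> np.ndarray:
        return self.ranges.starts

    @property
    def ends(self) -> np.ndarray:
        return self.ranges.ends

    @property
    def widths(self) -> np.ndarray:
        return self.ranges.widths

    @property
    def annotations(self) -> AnnotationTable:
        return self.ranges.annotations

    @property
    def names(self):
        return self.ranges.names

    def __len__(self) -> int:
        return len(self.ranges)

    def __getitem__(self, idx) -> "GenomicRanges":
        sub = self.ranges[idx]
        if isinstance(idx, np.ndarray) and idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        elif isinstance(idx, slice):
            idx = np.arange(len(self))[idx]
        else:
            idx = np.atleast_1d(np.asarray(idx, dtype=np.int64))
        return GenomicRanges(self.seq_names[idx], sub, self.strand[idx],
                             self.seq_info)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomicRanges):
            return NotImplemented
        return (np.array_equal(self.seq_names, other.seq_names)
                and self.ranges == other.ranges
                and np.array_equal(self.strand, other.strand))

    def __repr__(self) -> str:
        return (f"GenomicRanges({len(self)} ranges on "
                f"{len(set(self.seq_names.tolist()))} sequence(s))")

    def with_ranges(self, ranges: IntegerRanges) -> "GenomicRanges":
        return GenomicRanges(self.seq_names, ranges, self.strand, self.seq_info)

    def with_annotations(self, annotations) -> "GenomicRanges":
        r = IntegerRanges(self.ranges.starts, self.ranges.ends,
                          names=self.ranges.names, annotations=annotations)
        return self.with_ranges(r)

    def out_of_bounds(self) -> np.ndarray:
        """Mask of ranges extending past [1, seq length] where length known."""
        mask = np.zeros(len(self), dtype=bool)
        for i in range(len(self)):
            L = self.seq_info.seq_lengths.get(str(self.seq_names[i]))
            if self.starts[i] < 1 or (L is not None and self.ends[i] > L):
                mask[i] = True
        return mask


def concat_genomic(*gs: GenomicRanges) -> GenomicRanges:
    """Concatenate GenomicRanges sharing (or unioning) their SeqInfo."""
    if not gs:
        raise RangesError("concat_genomic needs at least one input")
    for g in gs[1:]:
        _check_same_build(gs[0].seq_info, g.seq_info, "concatenation")
    names: list[str] = []
    lengths: dict[str, int | None] = {}
    genome = next((g.seq_info.genome for g in gs if g.seq_info.genome), None)
    for g in gs:
        for n in g.seq_info.seq_names:
            if n not in lengths:
                names.append(n)
                lengths[n] = g.seq_info.seq_lengths[n]
    info = SeqInfo(names, {k: v for k, v in lengths.items() if v is not None},
                   genome=genome)
    return GenomicRanges(
        np.concatenate([g.seq_names for g in gs]),
        core.concat(*[g.ranges for g in gs]),
        np.concatenate([g.strand for g in gs]),
        info)


def flip_strand(g: GenomicRanges) -> GenomicRanges:
    flipped = np.array(["-" if s == "+" else "+" if s == "-" else "*"
                        for s in g.strand], dtype=object)
    return GenomicRanges(g.seq_names, g.ranges, flipped, g.seq_info)


def trim(g: GenomicRanges) -> GenomicRanges:
    """Clip ranges to [1, seq length] where the length is known."""
    starts = np.maximum(g.starts, 1)
    ends = g.ends.copy()
    for i in range(len(g)):
        L = g.seq_info.seq_lengths.get(str(g.seq_names[i]))
        if L is not None:
            ends[i] = min(ends[i], L)
    ends = np.maximum(ends, starts - 1)
    return g.with_ranges(g.ranges.replace(starts=starts, ends=ends))


def _strand_mirrored(g: GenomicRanges, op, *args, **kwargs) -> GenomicRanges:
    """Apply a core op with start/end anchors mirrored on '-' strand."""
    minus = g.strand == "-"
    plus_part = op(g.ranges, *args, **kwargs)
    swap = {"start": "end", "end": "start", "center": "center"}
    m_kwargs = dict(kwargs)
    for key in ("anchor", "side"):
        if key in m_kwargs:
            m_kwargs[key] = swap[m_kwargs[key]]
    minus_part = op(g.ranges, *args, **m_kwargs)
    starts = np.where(minus, minus_part.starts, plus_part.starts)
    ends = np.where(minus, minus_part.ends, plus_part.ends)
    return g.with_ranges(g.ranges.replace(starts=starts, ends=ends))


def genomic_resize(g: GenomicRanges, width: int,
                   anchor: str = "start") -> GenomicRanges:
    """Strand-aware resize: "start" is the 5' end, so on '-' strand it is the
    rightmost coordinate. '*' behaves as '+'."""
    return _strand_mirrored(g, core.resize, width, anchor=anchor)


def genomic_flank(g: GenomicRanges, width: int, side: str = "start",
                  both: bool = False) -> GenomicRanges:
    """Strand-aware flank: side="start" is upstream in transcription
    direction (promoter side)."""
    return _strand_mirrored(g, core.flank, width, side=side, both=both)


def _strand_compatible(a: str, b: str) -> bool:
    return a == "*" or b == "*" or a == b


def genomic_find_overlaps(query, subject, mode: str = "any", max_gap: int = 0,
                          min_overlap: int = 1,
                          ignore_strand: bool = False) -> Hits:
    """Overlaps between genomic ranges or grouped lists.

    Hits are confined to equal sequence names and compatible strands (unless
    ``ignore_strand``). List inputs report element-level hits: one hit per
    (query element, subject element) pair with any overlapping member pair.
    """
    q_list = isinstance(query, GenomicRangesList)
    s_list = isinstance(subject, GenomicRangesList)
    q_flat = query.flat if q_list else query
    s_flat = subject.flat if s_list else subject
    _check_same_build(q_flat.seq_info, s_flat.seq_info, "overlap detection")

    qi_out: list[int] = []
    si_out: list[int] = []
    q_seqs = q_flat.seq_names
    for seq in dict.fromkeys(q_seqs.tolist()):
        q_idx = np.nonzero(q_seqs == seq)[0]
        s_idx = np.nonzero(s_flat.seq_names == seq)[0]
        if s_idx.size == 0:
            continue
        hits = find_overlaps(q_flat.ranges[q_idx], s_flat.ranges[s_idx],
                             mode=mode, max_gap=max_gap,
                             min_overlap=min_overlap)
        for qh, sh in zip(hits.query_index, hits.subject_index):
            qi, si = int(q_idx[qh]), int(s_idx[sh])
            if not ignore_strand and not _strand_compatible(
                    str(q_flat.strand[qi]), str(s_flat.strand[si])):
                continue
            qi_out.append(qi)
            si_out.append(si)

    qi_arr = np.asarray(qi_out, dtype=np.int64)
    si_arr = np.asarray(si_out, dtype=np.int64)
    if q_list:
        qi_arr = query.partition.group_of()[qi_arr] if len(qi_arr) else qi_arr
    if s_list:
        si_arr = subject.partition.group_of()[si_arr] if len(si_arr) else si_arr
    if q_list or s_list:
        pairs = np.unique(np.stack([qi_arr, si_arr], axis=1), axis=0) \
            if len(qi_arr) else np.empty((0, 2), dtype=np.int64)
        qi_arr, si_arr = pairs[:, 0], pairs[:, 1]
    n_q = len(query) if not q_list else len(query.partition)
    n_s = len(subject) if not s_list else len(subject.partition)
    return Hits(qi_arr, si_arr, n_q, n_s)


def keep_seqlevels(g, names: Sequence[str]):
    """Drop ranges on other sequences and prune SeqInfo to ``names``.

    On a list, member ranges are dropped but groups (and their names) are
    retained, possibly empty, so feature keys stay stable.
    """
    if isinstance(g, GenomicRangesList):
        keep = np.isin(g.flat.seq_names, np.asarray(list(names), dtype=object))
        group_of = g.partition.group_of()
        new_flat = keep_seqlevels(g.flat, names)
        sizes = np.bincount(group_of[keep], minlength=len(g.partition))
        return GenomicRangesList(new_flat, sizes, names=g.names)
    info = g.seq_info.subset(list(names))
    keep = np.isin(g.seq_names, np.asarray(list(names), dtype=object))
    idx = np.nonzero(keep)[0]
    return GenomicRanges(g.seq_names[idx], g.ranges[idx], g.strand[idx], info)


def rename_seqlevels(g, mapping: Mapping[str, str]):
    """Rewrite sequence names consistently in SeqInfo and per range."""
    if isinstance(g, GenomicRangesList):
        return _list_map_flat(g, lambda f: rename_seqlevels(f, mapping))
    info = g.seq_info.rename(mapping)
    new_names = np.asarray([mapping.get(str(n), str(n)) for n in g.seq_names],
                           dtype=object)
    return GenomicRanges(new_names, g.ranges, g.strand, info)


class GenomicRangesList:
    """Compound genomic features: one flat GenomicRanges plus a partition."""

    def __init__(self, flat: GenomicRanges, sizes, names=None):
        self.flat = flat
        self.partition = RangesGrouping(flat.ranges, sizes, names=names)

    @classmethod
    def from_groups(cls, groups: Sequence[GenomicRanges],
                    names=None) -> "GenomicRangesList":
        if not groups:
            raise RangesError("from_groups needs at least one group")
        flat = concat_genomic(*groups)
        return cls(flat, [len(g) for g in groups], names=names)

    @property
    def names(self):
        return self.partition.names

    def __len__(self) -> int:
        return len(self.partition)

    def __getitem__(self, key) -> GenomicRanges:
        i = self.partition._resolve(key)
        lo = int(self.partition._offsets[i])
        hi = int(self.partition._offsets[i + 1])
        idx = np.arange(lo, hi)
        return self.flat[idx]

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __repr__(self) -> str:
        return (f"GenomicRangesList({len(self)} elements, "
                f"{len(self.flat)} ranges total)")

    def reduce_groups(self) -> "GenomicRangesList":
        """reduce() applied within each group, over the flat store."""
        groups = []
        for i in range(len(self)):
            g = self[i]
            merged, _ = core.reduce_ranges(g.ranges)
            n = len(merged)
            seqs = np.full(n, g.seq_names[0] if len(g) else "", dtype=object)
            strands = np.full(n, g.strand[0] if len(g) else "*", dtype=object)
            groups.append(GenomicRanges(seqs, merged, strands, g.seq_info))
        return GenomicRangesList.from_groups(groups, names=self.names)


def _list_map_flat(L: GenomicRangesList, fn) -> GenomicRangesList:
    """Apply a length-preserving flat-level transform, keeping the partition."""
    new_flat = fn(L.flat)
    if len(new_flat) != len(L.flat):
        raise RangesError("flat transform changed element count")
    return GenomicRangesList(new_flat, L.partition.sizes, names=L.names)


def group_genomic(g: GenomicRanges, factor) -> GenomicRangesList:
    """Group genomic ranges by a factor into a GenomicRangesList."""
    factor = np.asarray(factor, dtype=object)
    if len(factor) != len(g):
        raise RangesError("factor length mismatch")
    levels = list(dict.fromkeys(factor.tolist()))
    level_pos = {lv: i for i, lv in enumerate(levels)}
    order = np.argsort([level_pos[v] for v in factor], kind="stable")
    sizes = [int((factor == lv).sum()) for lv in levels]
    return GenomicRangesList(g[order], sizes, names=[str(lv) for lv in levels])


def list_extract(L: GenomicRangesList, key) -> GenomicRanges:
    """Extract one group as a standalone GenomicRanges."""
    return L[key]


def genomic_coverage(g: GenomicRanges) -> dict[str, RleVector]:
    """Per-sequence coverage (strand pooled), one RLE vector per sequence.

    Sequence lengths come from SeqInfo; where unknown they are inferred as
    the max end observed on that sequence.
    """
    out: dict[str, RleVector] = {}
    for seq in g.seq_info.seq_names:
        idx = np.nonzero(g.seq_names == seq)[0]
        L = g.seq_info.seq_lengths.get(seq)
        if L is None:
            L = int(g.ends[idx].max()) if idx.size else 0
        out[seq] = coverage(g.ranges[idx], L)
    return out
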