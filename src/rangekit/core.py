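"""Integer-range vectors and the plain (non-genomic) range algebra.

A *range* is an ordered set of consecutive integer positions stored as a
(start, end) pair, 1-based and closed on both sides; ``width = end - start + 1``.
A zero-width range (``end == start - 1``) is legal and models an insertion
point occupying no positions; zero-width ranges never produce overlap hits
and contribute nothing to coverage or set operations.

:class:`IntegerRanges` is the universal currency of the library: a vector of
ranges with optional per-range names and an :class:`AnnotationTable` of
per-range metadata. All operations are functional: they return new objects
and never mutate their inputs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationTable",
    "IntegerRanges",
    "RangesGrouping",
    "make_ranges",
    "shift",
    "resize",
    "flank",
    "restrict",
    "distance",
    "range_span",
    "reduce_ranges",
    "disjoin",
    "gaps",
    "set_union",
    "set_intersect",
    "set_setdiff",
    "p_union",
    "p_intersect",
    "p_setdiff",
    "p_gap",
    "order_ranges",
    "sort_ranges",
    "duplicated",
    "unique_ranges",
    "split_ranges",
    "concat",
]


class RangesError(ValueError):
    """Raised when range data violates a structural invariant."""


def _as_int_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.int64)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.ndim != 1:
        raise RangesError(f"{name} must be one-dimensional")
    return arr


class AnnotationTable:
    """Per-element metadata: named columns, one row per range.

    Columns may hold numbers, text, booleans, or opaque payloads (including
    nested range objects) via object dtype. Backed by a pandas DataFrame with
    a plain positional index.
    """

    def __init__(self, columns: Mapping[str, Sequence] | pd.DataFrame | None = None,
                 n_rows: int | None = None):
        if columns is None:
            if n_rows is None:
                n_rows = 0
            self._df = pd.DataFrame(index=pd.RangeIndex(n_rows))
        elif isinstance(columns, pd.DataFrame):
            if columns.columns.has_duplicates:
                raise RangesError("annotation column names must be unique")
            self._df = columns.reset_index(drop=True)
        else:
            cols = dict(columns)
            if not cols and n_rows is not None:
                self._df = pd.DataFrame(index=pd.RangeIndex(n_rows))
            else:
                self._df = pd.DataFrame(cols)
        if n_rows is not None and len(self._df) != n_rows:
            raise RangesError(
                f"annotation table has {len(self._df)} rows, expected {n_rows}")

    @property
    def n_rows(self) -> int:
        return len(self._df)

    @property
    def column_names(self) -> list[str]:
        return list(self._df.columns)

    def column(self, name: str) -> np.ndarray:
        if name not in self._df.columns:
            raise KeyError(f"no annotation column {name!r}")
        return self._df[name].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def subset(self, idx) -> "AnnotationTable":
        return AnnotationTable(self._df.iloc[idx].reset_index(drop=True))

    def with_column(self, name: str, values: Sequence) -> "AnnotationTable":
        df = self._df.copy()
        df[name] = list(values)
        return AnnotationTable(df)

    @staticmethod
    def concat(tables: Sequence["AnnotationTable"]) -> "AnnotationTable":
        if not tables:
            return AnnotationTable()
        frames = [t._df for t in tables]
        return AnnotationTable(pd.concat(frames, ignore_index=True))

    def equals(self, other: "AnnotationTable") -> bool:
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"AnnotationTable({self.n_rows} rows x {len(self._df.columns)} cols)"


class IntegerRanges:
    """A vector of 1-based closed integer intervals.

    Parameters
    ----------
    starts, ends
        Equal-length integer vectors with ``ends[i] >= starts[i] - 1``
        (width 0 encodes an empty range).
    names
        Optional per-range names.
    annotations
        Optional :class:`AnnotationTable` (or column mapping) with one row
        per range.
    """

    def __init__(self, starts, ends, names=None, annotations=None):
        starts = _as_int_array(starts, "starts")
        ends = _as_int_array(ends, "ends")
        if len(starts) != len(ends):
            raise RangesError(
                f"starts length {len(starts)} != ends length {len(ends)}")
        bad = np.nonzero(ends < starts - 1)[0]
        if bad.size:
            i = int(bad[0])
            raise RangesError(
                f"negative width at index {i}: start={starts[i]}, end={ends[i]}")
        starts.flags.writeable = False
        ends.flags.writeable = False
        self._starts = starts
        self._ends = ends
        if names is not None:
            names = np.asarray(names, dtype=object)
            if len(names) != len(starts):
                raise RangesError("names length mismatch")
        self._names = names
        if annotations is None:
            annotations = AnnotationTable(n_rows=len(starts))
        elif not isinstance(annotations, AnnotationTable):
            annotations = AnnotationTable(annotations, n_rows=len(starts))
        elif annotations.n_rows != len(starts):
            raise RangesError("annotation row count mismatch")
        self._annotations = annotations

    # -- accessors ---------------------------------------------------------

    @property
    def starts(self) -> np.ndarray:
        return self._starts

    @property
    def ends(self) -> np.ndarray:
        return self._ends

    @property
    def widths(self) -> np.ndarray:
        return self._ends - self._starts + 1

    @property
    def names(self) -> np.ndarray | None:
        return self._names

    @property
    def annotations(self) -> AnnotationTable:
        return self._annotations

    def __len__(self) -> int:
        return len(self._starts)

    def __repr__(self) -> str:
        n = len(self)
        shown = ", ".join(f"[{s}, {e}]" for s, e in
                          zip(self._starts[:4], self._ends[:4]))
        more = ", ..." if n > 4 else ""
        return f"IntegerRanges({n} ranges: {shown}{more})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntegerRanges):
            return NotImplemented
        if len(self) != len(other):
            return False
        same = (np.array_equal(self._starts, other._starts)
                and np.array_equal(self._ends, other._ends))
        if not same:
            return False
        if (self._names is None) != (other._names is None):
            return False
        if self._names is not None and not np.array_equal(self._names, other._names):
            return False
        return True

    # -- extraction --------------------------------------------------------

    def __getitem__(self, idx) -> "IntegerRanges":
        """Extract by boolean mask, integer vector, scalar, or slice.

        Names and annotation rows travel row-wise with the ranges.
        """
        if isinstance(idx, (int, np.integer)):
            idx = [int(idx)]
        idx = np.asarray(idx) if not isinstance(idx, slice) else idx
        if isinstance(idx, np.ndarray) and idx.dtype == bool:
            if len(idx) != len(self):
                raise IndexError("boolean mask length mismatch")
            idx = np.nonzero(idx)[0]
        if isinstance(idx, slice):
            idx = np.arange(len(self))[idx]
        else:
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < -len(self) or idx.max() >= len(self)):
                raise IndexError(f"range index out of bounds (n={len(self)})")
        names = self._names[idx] if self._names is not None else None
        return IntegerRanges(self._starts[idx], self._ends[idx], names=names,
                             annotations=self._annotations.subset(idx))

    def element_sequence(self, i: int) -> np.ndarray:
        """The integer positions start[i]..end[i] (empty for width 0)."""
        if not 0 <= i < len(self):
            raise IndexError(f"range index {i} out of bounds (n={len(self)})")
        return np.arange(self._starts[i], self._ends[i] + 1)

    def head(self, n: int = 6) -> "IntegerRanges":
        return self[np.arange(min(n, len(self)))]

    def tail(self, n: int = 6) -> "IntegerRanges":
        k = min(n, len(self))
        return self[np.arange(len(self) - k, len(self))]

    def rev(self) -> "IntegerRanges":
        return self[np.arange(len(self))[::-1]]

    def replace(self, starts=None, ends=None) -> "IntegerRanges":
        """New vector with coordinates swapped out, metadata retained."""
        return IntegerRanges(
            self._starts if starts is None else starts,
            self._ends if ends is None else ends,
            names=self._names, annotations=self._annotations)

    def position_set(self) -> set[int]:
        """All covered integer positions (for small ranges; testing aid)."""
        out: set[int] = set()
        for s, e in zip(self._starts, self._ends):
            out.update(range(int(s), int(e) + 1))
        return out


def make_ranges(starts, ends=None, *, widths=None, names=None,
                annotations=None) -> IntegerRanges:
    """Construct an :class:`IntegerRanges` from starts plus ends or widths."""
    if (ends is None) == (widths is None):
        raise RangesError("provide exactly one of ends= or widths=")
    starts = _as_int_array(starts, "starts")
    if widths is not None:
        widths = _as_int_array(widths, "widths")
        if len(widths) != len(starts):
            raise RangesError("widths length mismatch")
        bad = np.nonzero(widths < 0)[0]
        if bad.size:
            raise RangesError(f"negative width at index {int(bad[0])}")
        ends = starts + widths - 1
    return IntegerRanges(starts, ends, names=names, annotations=annotations)


# -- arithmetic -------------------------------------------------------------


def shift(r: IntegerRanges, amount) -> IntegerRanges:
    """Translate every range by ``amount`` (scalar or per-range vector)."""
    amount = np.asarray(amount, dtype=np.int64)
    if amount.ndim == 1 and len(amount) != len(r):
        raise RangesError(
            f"amount length {len(amount)} != number of ranges {len(r)}")
    return r.replace(starts=r.starts + amount, ends=r.ends + amount)


def resize(r: IntegerRanges, width: int, anchor: str = "start") -> IntegerRanges:
    """Set every range's width, holding one coordinate fixed.

    ``anchor="start"`` fixes the start, ``"end"`` the end, ``"center"`` the
    midpoint with the tie-break ``new_start = start + (old_width - width) // 2``
    (floor division: an odd width change puts the extra base on the right).
    """
    if width < 0:
        raise RangesError("width must be >= 0")
    if anchor == "start":
        starts = r.starts
    elif anchor == "end":
        starts = r.ends - width + 1
    elif anchor == "center":
        starts = r.starts + (r.widths - width) // 2
    else:
        raise RangesError(f"unknown anchor {anchor!r}")
    return r.replace(starts=starts, ends=starts + width - 1)


def flank(r: IntegerRanges, width: int, side: str = "start",
          both: bool = False) -> IntegerRanges:
    """Regions adjacent to each range on the given side.

    ``side="start"`` yields ``[start - width, start - 1]``; ``side="end"``
    yields ``[end + 1, end + width]``. With ``both=True`` the flank straddles
    the anchor boundary, extending ``width`` on each side of it:
    start-side -> ``[start - width, start + width - 1]``.
    """
    if width < 0:
        raise RangesError("width must be >= 0")
    if side == "start":
        if both:
            starts, ends = r.starts - width, r.starts + width - 1
        else:
            starts, ends = r.starts - width, r.starts - 1
    elif side == "end":
        if both:
            starts, ends = r.ends - width + 1, r.ends + width
        else:
            starts, ends = r.ends + 1, r.ends + width
    else:
        raise RangesError(f"unknown side {side!r}")
    return r.replace(starts=starts, ends=ends)


def restrict(r: IntegerRanges, lo: int, hi: int):
    """Clamp ranges to [lo, hi]; ranges that vanish are dropped.

    Returns ``(clamped, kept_index)`` where ``kept_index`` maps each output
    row to the input row it came from.
    """
    if lo > hi + 1:
        raise RangesError("restrict bounds require lo <= hi + 1")
    starts = np.maximum(r.starts, lo)
    ends = np.minimum(r.ends, hi)
    keep = np.nonzero(ends >= starts)[0]
    clamped = r[keep].replace(starts=starts[keep], ends=ends[keep])
    return clamped, keep


def distance(r1: IntegerRanges, r2: IntegerRanges) -> np.ndarray:
    """Element-wise separation: the count of positions strictly between each
    pair; 0 for overlapping or adjacent ranges."""
    if len(r1) != len(r2):
        raise RangesError("distance requires equal-length range vectors")
    gap = np.maximum(r1.starts, r2.starts) - np.minimum(r1.ends, r2.ends) - 1
    return np.maximum(gap, 0)


def range_span(r: IntegerRanges) -> IntegerRanges:
    """The single range [min start, max end]; empty input -> empty result."""
    live = r.widths > 0
    src = r[live] if not live.all() else r
    if len(src) == 0:
        if len(r) == 0:
            return IntegerRanges([], [])
        src = r  # all zero-width: span of the stored endpoints
    return IntegerRanges([int(src.starts.min())], [int(src.ends.max())])


# -- inter-range (set-like) operations --------------------------------------


def reduce_ranges(r: IntegerRanges, min_gap: int = 0):
    """Merge overlapping and adjacent ranges into a minimal sorted set.

    Ranges separated by ``<= min_gap`` positions are merged (``min_gap=0``
    still merges adjacent ranges). Zero-width inputs cover no positions and
    are dropped. Returns ``(merged, index_map)`` with ``index_map[i]`` the
    output range that input ``i`` landed in (-1 for dropped zero-width rows).
    """
    if min_gap < 0:
        raise RangesError("min_gap must be >= 0")
    index_map = np.full(len(r), -1, dtype=np.int64)
    live = np.nonzero(r.widths > 0)[0]
    if live.size == 0:
        return IntegerRanges([], []), index_map
    order = live[np.argsort(r.starts[live], kind="stable")]
    out_s, out_e = [], []
    for i in order:
        s, e = int(r.starts[i]), int(r.ends[i])
        if out_s and s <= out_e[-1] + 1 + min_gap:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
        index_map[i] = len(out_s) - 1
    return IntegerRanges(out_s, out_e), index_map


def disjoin(r: IntegerRanges):
    """Partition the covered positions at every input endpoint.

    Returns ``(pieces, covers)``: the smallest sorted set of disjoint ranges
    such that each input is a union of pieces, plus, for each piece, the
    array of input indices covering it (constant along the piece).
    """
    live = np.nonzero(r.widths > 0)[0]
    if live.size == 0:
        return IntegerRanges([], []), []
    s, e = r.starts[live], r.ends[live]
    bounds = np.unique(np.concatenate([s, e + 1]))
    piece_s, piece_e, covers = [], [], []
    for lo, hi in zip(bounds[:-1], bounds[1:] - 1):
        mask = (s <= lo) & (e >= hi)
        if mask.any():
            piece_s.append(int(lo))
            piece_e.append(int(hi))
            covers.append(live[np.nonzero(mask)[0]])
    return IntegerRanges(piece_s, piece_e), covers


def gaps(r: IntegerRanges, lo: int, hi: int) -> IntegerRanges:
    """The complement of ``reduce(r)`` within [lo, hi]."""
    if lo > hi:
        raise RangesError("gaps bounds require lo <= hi")
    merged, _ = reduce_ranges(r)
    merged, _ = restrict(merged, lo, hi)
    out_s, out_e = [], []
    cursor = lo
    for s, e in zip(merged.starts, merged.ends):
        if s > cursor:
            out_s.append(cursor)
            out_e.append(int(s) - 1)
        cursor = int(e) + 1
    if cursor <= hi:
        out_s.append(cursor)
        out_e.append(hi)
    return IntegerRanges(out_s, out_e)


def _merged_pairs(r: IntegerRanges) -> list[tuple[int, int]]:
    m, _ = reduce_ranges(r)
    return list(zip(m.starts.tolist(), m.ends.tolist()))


def set_union(x: IntegerRanges, y: IntegerRanges) -> IntegerRanges:
    """Reduced ranges covering the union of covered positions."""
    merged, _ = reduce_ranges(concat(x, y))
    return merged


def set_intersect(x: IntegerRanges, y: IntegerRanges) -> IntegerRanges:
    """Reduced ranges covering the intersection of covered positions."""
    xs, ys = _merged_pairs(x), _merged_pairs(y)
    out_s, out_e = [], []
    i = j = 0
    while i < len(xs) and j < len(ys):
        s = max(xs[i][0], ys[j][0])
        e = min(xs[i][1], ys[j][1])
        if s <= e:
            out_s.append(s)
            out_e.append(e)
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    merged, _ = reduce_ranges(IntegerRanges(out_s, out_e))
    return merged


def set_setdiff(x: IntegerRanges, y: IntegerRanges) -> IntegerRanges:
    """Reduced ranges covering positions in x but not in y."""
    out_s, out_e = [], []
    ys = _merged_pairs(y)
    for s, e in _merged_pairs(x):
        cursor = s
        for ys_, ye_ in ys:
            if ye_ < cursor or ys_ > e:
                continue
            if ys_ > cursor:
                out_s.append(cursor)
                out_e.append(ys_ - 1)
            cursor = max(cursor, ye_ + 1)
            if cursor > e:
                break
        if cursor <= e:
            out_s.append(cursor)
            out_e.append(e)
    return IntegerRanges(out_s, out_e)


# -- parallel (element-wise) set operations ---------------------------------


def _check_parallel(x: IntegerRanges, y: IntegerRanges, op: str):
    if len(x) != len(y):
        raise RangesError(f"{op} requires equal-length range vectors")


def p_union(x: IntegerRanges, y: IntegerRanges) -> IntegerRanges:
    """Element-wise union; each pair must overlap or be adjacent."""
    _check_parallel(x, y, "p_union")
    gap = np.maximum(x.starts, y.starts) - np.minimum(x.ends, y.ends) - 1
    bad = np.nonzero(gap > 0)[0]
    if bad.size:
        raise RangesError(
            f"p_union of disjoint, non-adjacent pair at index {int(bad[0])}")
    return IntegerRanges(np.minimum(x.starts, y.starts),
                         np.maximum(x.ends, y.ends))


def p_intersect(x: IntegerRanges, y: IntegerRanges) -> IntegerRanges:
    """Element-wise intersection (zero-width when the pair is disjoint)."""
    _check_parallel(x, y, "p_intersect")
    s = np.maximum(x.starts, y.starts)
    e = np.minimum(x.ends, y.ends)
    e = np.maximum(e, s - 1)  # disjoint pair -> zero-width at s
    return IntegerRanges(s, e)


def p_setdiff(x: IntegerRanges, y: IntegerRanges) -> IntegerRanges:
    """Element-wise x minus y where the result is a single range.

    Errors when y splits x into two pieces (a single range cannot represent
    that); use :func:`set_setdiff` per element instead.
    """
    _check_parallel(x, y, "p_setdiff")
    out_s = x.starts.copy()
    out_e = x.ends.copy()
    for i in range(len(x)):
        xs, xe = int(x.starts[i]), int(x.ends[i])
        ys, ye = int(y.starts[i]), int(y.ends[i])
        if ye < ys or ye < xs or ys > xe:      # no overlap
            continue
        if ys <= xs and ye >= xe:              # y covers x -> zero-width
            out_s[i], out_e[i] = xs, xs - 1
        elif ys <= xs:                         # trim left
            out_s[i] = ye + 1
        elif ye >= xe:                         # trim right
            out_e[i] = ys - 1
        else:
            raise RangesError(
                f"p_setdiff result at index {i} is not a single range")
    return IntegerRanges(out_s, out_e)


def p_gap(x: IntegerRanges, y: IntegerRanges) -> IntegerRanges:
    """The range strictly between each pair (zero-width if none)."""
    _check_parallel(x, y, "p_gap")
    s = np.minimum(x.ends, y.ends) + 1
    e = np.maximum(x.starts, y.starts) - 1
    zero = e < s - 1
    e = np.where(zero, s - 1, e)
    return IntegerRanges(s, e)


# -- ordering ----------------------------------------------------------------


def order_ranges(r: IntegerRanges) -> np.ndarray:
    """Stable permutation sorting by (start, width)."""
    return np.lexsort((r.widths, r.starts))


def sort_ranges(r: IntegerRanges) -> IntegerRanges:
    return r[order_ranges(r)]


def duplicated(r: IntegerRanges) -> np.ndarray:
    """True for later instances of an identical (start, end) pair."""
    df = pd.DataFrame({"s": r.starts, "e": r.ends})
    return df.duplicated().to_numpy()


def unique_ranges(r: IntegerRanges) -> IntegerRanges:
    return r[~duplicated(r)]


# -- split / combine ---------------------------------------------------------


class RangesGrouping:
    """An ordered partition of a flat :class:`IntegerRanges`.

    The flat vector is stored once; groups are contiguous runs described by
    per-group sizes. Concatenating the groups in order reproduces the flat
    vector exactly.
    """

    def __init__(self, flat: IntegerRanges, sizes, names=None):
        sizes = _as_int_array(sizes, "sizes")
        if sizes.sum() != len(flat):
            raise RangesError("group sizes do not sum to flat length")
        if (sizes < 0).any():
            raise RangesError("group sizes must be >= 0")
        self._flat = flat
        self._sizes = sizes
        self._offsets = np.concatenate([[0], np.cumsum(sizes)])
        if names is not None:
            names = [str(n) for n in names]
            if len(names) != len(sizes):
                raise RangesError("group names length mismatch")
        self._names = names

    @property
    def flat(self) -> IntegerRanges:
        return self._flat

    @property
    def sizes(self) -> np.ndarray:
        return self._sizes

    @property
    def names(self) -> list[str] | None:
        return self._names

    def __len__(self) -> int:
        return len(self._sizes)

    def group_of(self) -> np.ndarray:
        """Group id of each flat element."""
        return np.repeat(np.arange(len(self._sizes)), self._sizes)

    def _resolve(self, key) -> int:
        if isinstance(key, str):
            if self._names is None or key not in self._names:
                raise KeyError(f"no group named {key!r}")
            return self._names.index(key)
        i = int(key)
        if not 0 <= i < len(self):
            raise IndexError(f"group index {i} out of bounds")
        return i

    def __getitem__(self, key) -> IntegerRanges:
        i = self._resolve(key)
        lo, hi = self._offsets[i], self._offsets[i + 1]
        return self._flat[np.arange(lo, hi)]

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def split_ranges(r: IntegerRanges, factor) -> RangesGrouping:
    """Group ranges by a factor; levels in order of first appearance."""
    factor = np.asarray(factor, dtype=object)
    if len(factor) != len(r):
        raise RangesError("factor length mismatch")
    levels: list = []
    seen = {}
    for v in factor:
        if v not in seen:
            seen[v] = len(levels)
            levels.append(v)
    order = np.argsort([seen[v] for v in factor], kind="stable")
    sizes = [int((factor == lv).sum()) for lv in levels]
    return RangesGrouping(r[order], sizes, names=[str(lv) for lv in levels])


def concat(*rs: IntegerRanges) -> IntegerRanges:
    """Concatenate range vectors; names and annotations ride along."""
    if not rs:
        return IntegerRanges([], [])
    starts = np.concatenate([r.starts for r in rs])
    ends = np.concatenate([r.ends for r in rs])
    if any(r.names is not None for r in rs):
        names = np.concatenate([
            r.names if r.names is not None else np.full(len(r), None, dtype=object)
            for r in rs])
    else:
        names = None
    annotations = AnnotationTable.concat([r.annotations for r in rs])
    return IntegerRanges(starts, ends, names=names, annotations=annotations)
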