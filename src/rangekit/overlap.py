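"""Overlap detection and nearest-neighbour queries on range vectors.

The subject vector is indexed once into an :class:`IntervalIndex` — ranges
sorted by start plus a segment tree over their ends — giving O(n log n)
construction and O(log n + hits) window queries. Batch queries walk the same
structure without rebuilding anything per query. A fingerprint of the indexed
coordinates is checked on every query so that a stale index (subject swapped
out from under it) raises instead of silently answering for the wrong data.

Overlap semantics: a pair hits in mode ``any`` when the overlap width is at
least ``min_overlap``, or, when ``max_gap > 0``, when the separation between
the ranges is at most ``max_gap``. ``within`` requires the query to be a
subregion of the subject; ``equal`` requires identical endpoints. ``max_gap``
applies only to mode ``any``; ``min_overlap`` applies to every mode, so
zero-width ranges never hit at the defaults. Adjacency is not overlap at the
defaults.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .core import IntegerRanges, RangesError

__all__ = [
    "IntervalIndex",
    "Hits",
    "build_index",
    "find_overlaps",
    "count_overlaps",
    "subset_by_overlaps",
    "nearest",
    "precede",
    "follow",
    "NO_HIT",
]

NO_HIT = -1  # sentinel subject index for "no neighbour exists"

_MODES = ("any", "within", "equal")


def _fingerprint(r: IntegerRanges) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(r.starts).tobytes())
    h.update(np.ascontiguousarray(r.ends).tobytes())
    return h.hexdigest()


class Hits:
    """Sorted parallel vectors of (query_index, subject_index) pairs."""

    def __init__(self, query_index, subject_index, n_query: int, n_subject: int):
        q = np.asarray(query_index, dtype=np.int64)
        s = np.asarray(subject_index, dtype=np.int64)
        if len(q) != len(s):
            raise RangesError("hit vectors must be parallel")
        order = np.lexsort((s, q))
        self.query_index = q[order]
        self.subject_index = s[order]
        self.n_query = int(n_query)
        self.n_subject = int(n_subject)
        if len(q) and (self.query_index.min() < 0
                       or self.query_index.max() >= n_query
                       or self.subject_index.min() < 0
                       or self.subject_index.max() >= n_subject):
            raise RangesError("hit indices out of bounds")

    def __len__(self) -> int:
        return len(self.query_index)

    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.query_index.tolist(), self.subject_index.tolist()))

    def __repr__(self) -> str:
        return (f"Hits({len(self)} hits over {self.n_query} queries x "
                f"{self.n_subject} subjects)")


class IntervalIndex:
    """Search index over a subject range vector.

    Stores the subject sorted by start and a perfect binary segment tree of
    range-maximum ends, enabling enumeration of every subject with
    ``start <= hi and end >= lo`` in O(log n + hits).
    """

    def __init__(self, subject: IntegerRanges):
        self._subject = subject
        self._fp = _fingerprint(subject)
        n = len(subject)
        order = np.argsort(subject.starts, kind="stable")
        self._order = order
        self._starts = subject.starts[order]
        self._ends = subject.ends[order]
        size = 1
        while size < max(n, 1):
            size *= 2
        tree = np.full(2 * size, np.iinfo(np.int64).min, dtype=np.int64)
        tree[size:size + n] = self._ends
        for i in range(size - 1, 0, -1):
            tree[i] = max(tree[2 * i], tree[2 * i + 1])
        self._tree = tree
        self._size = size
        self._n = n

    @property
    def subject(self) -> IntegerRanges:
        return self._subject

    def check_fresh(self):
        if _fingerprint(self._subject) != self._fp:
            raise RangesError(
                "interval index is stale: subject ranges changed after build")

    def window(self, lo: int, hi: int) -> np.ndarray:
        """Original subject indices with start <= hi and end >= lo."""
        if self._n == 0:
            return np.empty(0, dtype=np.int64)
        k = int(np.searchsorted(self._starts, hi, side="right"))
        if k == 0:
            return np.empty(0, dtype=np.int64)
        out: list[int] = []
        tree, size = self._tree, self._size
        # descend: visit only nodes overlapping [0, k) with max end >= lo
        stack = [(1, 0, size)]
        while stack:
            node, nlo, nhi = stack.pop()
            if nlo >= k or tree[node] < lo:
                continue
            if nhi - nlo == 1:
                out.append(nlo)
                continue
            mid = (nlo + nhi) // 2
            stack.append((2 * node + 1, mid, nhi))
            stack.append((2 * node, nlo, mid))
        return self._order[np.asarray(out, dtype=np.int64)]


def build_index(subject: IntegerRanges) -> IntervalIndex:
    return IntervalIndex(subject)


def _hit_any(qs, qe, ss, se, max_gap, min_overlap) -> bool:
    ov = min(qe, se) - max(qs, ss) + 1
    if ov >= min_overlap:
        return True
    return max_gap > 0 and -ov <= max_gap and qe >= qs and se >= ss


def find_overlaps(query: IntegerRanges, subject: IntegerRanges | IntervalIndex,
                  mode: str = "any", max_gap: int = 0,
                  min_overlap: int = 1) -> Hits:
    """All (query, subject) pairs related under the requested overlap mode."""
    if mode not in _MODES:
        raise RangesError(f"unknown overlap mode {mode!r}; use any/within/equal")
    if max_gap < 0:
        raise RangesError("max_gap must be >= 0")
    if min_overlap < 1:
        raise RangesError("min_overlap must be >= 1")
    if isinstance(subject, IntervalIndex):
        index = subject
        index.check_fresh()
        subject = index.subject
    else:
        index = IntervalIndex(subject)
    qi_out: list[int] = []
    si_out: list[int] = []
    s_starts, s_ends = subject.starts, subject.ends
    for qi in range(len(query)):
        qs, qe = int(query.starts[qi]), int(query.ends[qi])
        if mode == "any":
            # separation <= max_gap admits subjects starting at qe+max_gap+1
            pad = max_gap + 1 if max_gap > 0 else 0
            cands = index.window(qs - pad, qe + pad)
            for si in cands:
                if _hit_any(qs, qe, int(s_starts[si]), int(s_ends[si]),
                            max_gap, min_overlap):
                    qi_out.append(qi)
                    si_out.append(int(si))
        else:
            # containment/equality candidates must span the query
            cands = index.window(qe, qs)
            for si in cands:
                ss, se = int(s_starts[si]), int(s_ends[si])
                ov = min(qe, se) - max(qs, ss) + 1
                if ov < min_overlap:
                    continue
                if mode == "within" and ss <= qs and se >= qe:
                    qi_out.append(qi)
                    si_out.append(int(si))
                elif mode == "equal" and ss == qs and se == qe:
                    qi_out.append(qi)
                    si_out.append(int(si))
    return Hits(qi_out, si_out, len(query), len(subject))


def count_overlaps(query: IntegerRanges, subject: IntegerRanges | IntervalIndex,
                   mode: str = "any", max_gap: int = 0,
                   min_overlap: int = 1) -> np.ndarray:
    """Per-query hit counts (row-wise tally of :func:`find_overlaps`)."""
    hits = find_overlaps(query, subject, mode=mode, max_gap=max_gap,
                         min_overlap=min_overlap)
    return np.bincount(hits.query_index, minlength=hits.n_query).astype(np.int64)


def subset_by_overlaps(query: IntegerRanges,
                       subject: IntegerRanges | IntervalIndex,
                       mode: str = "any", max_gap: int = 0,
                       min_overlap: int = 1) -> IntegerRanges:
    """Query elements with at least one hit, in original order."""
    counts = count_overlaps(query, subject, mode=mode, max_gap=max_gap,
                            min_overlap=min_overlap)
    return query[counts > 0]


def _pair_distance(qs, qe, ss, se) -> int:
    return max(0, max(qs, ss) - min(qe, se) - 1)


def nearest(query: IntegerRanges, subject: IntegerRanges,
            all_ties: bool = False):
    """Index of the closest subject per query (0 distance for overlap).

    Ties are broken toward the lowest subject index; ``all_ties=True``
    instead returns a list of arrays of all co-minimal subject indices.
    Empty subject -> ``NO_HIT`` sentinel (empty array under ``all_ties``).
    """
    n_q, n_s = len(query), len(subject)
    out = np.full(n_q, NO_HIT, dtype=np.int64)
    ties: list[np.ndarray] = []
    for qi in range(n_q):
        if n_s == 0:
            ties.append(np.empty(0, dtype=np.int64))
            continue
        gap = (np.maximum(query.starts[qi], subject.starts)
               - np.minimum(query.ends[qi], subject.ends) - 1)
        d = np.maximum(gap, 0)
        best = d.min()
        winners = np.nonzero(d == best)[0]
        out[qi] = winners[0]
        ties.append(winners)
    return ties if all_ties else out


def precede(query: IntegerRanges, subject: IntegerRanges) -> np.ndarray:
    """For each query, the nearest subject that starts after the query ends
    (the subject the query precedes); ``NO_HIT`` when none exists."""
    out = np.full(len(query), NO_HIT, dtype=np.int64)
    for qi in range(len(query)):
        after = np.nonzero(subject.starts > query.ends[qi])[0]
        if after.size:
            d = subject.starts[after] - query.ends[qi] - 1
            best = after[d == d.min()]
            out[qi] = best[0]
    return out


def follow(query: IntegerRanges, subject: IntegerRanges) -> np.ndarray:
    """For each query, the nearest subject that ends before the query starts
    (the subject the query follows); ``NO_HIT`` when none exists."""
    out = np.full(len(query), NO_HIT, dtype=np.int64)
    for qi in range(len(query)):
        before = np.nonzero(subject.ends < query.starts[qi])[0]
        if before.size:
            d = query.starts[qi] - subject.ends[before] - 1
            best = before[d == d.min()]
            out[qi] = best[0]
    return out
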