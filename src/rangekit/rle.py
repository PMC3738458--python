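"""Run-length-encoded vectors, coverage, peak slicing and Views.

Genome-length signals (per-position read coverage, conservation scores) are
mostly constant over long stretches, so they are stored as (value, run
length) pairs in canonical form: no zero-length runs, no equal adjacent
values. Coverage is computed event-wise from range endpoints, never by
materializing a position-per-element array, so chromosome-scale domains cost
O(n log n) in the number of ranges.

A :class:`Views` object binds a set of ranges to an RLE subject, supporting
per-range summaries (sums, maxima) — the bridge between range-based and
vector-based data.
"""

from __future__ import annotations

import numpy as np

from .core import IntegerRanges, RangesError

__all__ = [
    "RleVector",
    "Views",
    "rle_encode",
    "rle_decode",
    "coverage",
    "which_max",
    "extract_range",
    "slice_above",
    "view_sums",
    "view_maxs",
]


class RleVector:
    """A run-length-encoded vector in canonical form."""

    def __init__(self, run_values, run_lengths):
        values = np.asarray(run_values)
        lengths = np.asarray(run_lengths, dtype=np.int64)
        if values.shape != lengths.shape or values.ndim != 1:
            raise RangesError("run values and lengths must be parallel vectors")
        if (lengths <= 0).any():
            raise RangesError("run lengths must be positive")
        # canonicalize: merge equal adjacent runs
        if len(values) > 1:
            keep = np.concatenate([[True], values[1:] != values[:-1]])
            if not keep.all():
                idx = np.nonzero(keep)[0]
                values = values[idx]
                lengths = np.add.reduceat(lengths, idx)
        self.run_values = values
        self.run_lengths = lengths
        self._ends = np.cumsum(lengths)  # 1-based end position of each run

    @property
    def total_length(self) -> int:
        return int(self._ends[-1]) if len(self._ends) else 0

    @property
    def n_runs(self) -> int:
        return len(self.run_values)

    def __len__(self) -> int:
        return self.total_length

    def __eq__(self, other) -> bool:
        if not isinstance(other, RleVector):
            return NotImplemented
        return (np.array_equal(self.run_values, other.run_values)
                and np.array_equal(self.run_lengths, other.run_lengths))

    def __repr__(self) -> str:
        return (f"RleVector(length {self.total_length}, "
                f"{self.n_runs} runs)")

    def value_at(self, pos: int):
        """Value at 1-based position ``pos``."""
        if not 1 <= pos <= self.total_length:
            raise IndexError(f"position {pos} outside [1, {self.total_length}]")
        run = int(np.searchsorted(self._ends, pos, side="left"))
        return self.run_values[run]

    def max(self):
        if self.total_length == 0:
            raise RangesError("max of an empty RleVector")
        return self.run_values.max()

    def sum(self):
        return (self.run_values * self.run_lengths).sum()

    def _binary(self, other, op) -> "RleVector":
        if not isinstance(other, RleVector):
            other = RleVector([other], [max(self.total_length, 1)])
        if other.total_length != self.total_length:
            raise RangesError("RleVector arithmetic requires equal lengths")
        bounds = np.union1d(self._ends, other._ends)
        starts = np.concatenate([[0], bounds[:-1]])
        a = self.run_values[np.searchsorted(self._ends, starts, side="right")]
        b = other.run_values[np.searchsorted(other._ends, starts, side="right")]
        return RleVector(op(a, b), bounds - starts)

    def __add__(self, other):
        return self._binary(other, np.add)

    def __sub__(self, other):
        return self._binary(other, np.subtract)

    def __mul__(self, other):
        return self._binary(other, np.multiply)


def rle_encode(values) -> RleVector:
    """Encode a plain vector; equal adjacent values merge into one run."""
    values = np.asarray(values)
    if values.size == 0:
        return RleVector(np.empty(0, dtype=values.dtype if values.dtype != object
                                  else np.int64),
                         np.empty(0, dtype=np.int64))
    change = np.concatenate([[True], values[1:] != values[:-1]])
    idx = np.nonzero(change)[0]
    lengths = np.diff(np.concatenate([idx, [len(values)]]))
    return RleVector(values[idx], lengths)


def rle_decode(r: RleVector) -> np.ndarray:
    """Materialize the full vector (inverse of :func:`rle_encode`)."""
    return np.repeat(r.run_values, r.run_lengths)


def coverage(r: IntegerRanges, domain_length: int) -> RleVector:
    """Per-position count of ranges covering each position of [1, L].

    Ranges are clipped to the domain before counting; zero-width ranges
    contribute nothing. Computed from sorted endpoint events, so the domain
    may be chromosome-sized.
    """
    if domain_length < 0:
        raise RangesError("domain_length must be >= 0")
    L = int(domain_length)
    if L == 0:
        return RleVector(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    s = np.maximum(r.starts, 1)
    e = np.minimum(r.ends, L)
    keep = e >= s
    s, e = s[keep], e[keep]
    bounds = np.unique(np.concatenate([s, e + 1, [1, L + 1]]))
    delta = np.zeros(len(bounds), dtype=np.int64)
    np.add.at(delta, np.searchsorted(bounds, s), 1)
    np.add.at(delta, np.searchsorted(bounds, e + 1), -1)
    values = np.cumsum(delta)[:-1]
    lengths = np.diff(bounds)
    return RleVector(values, lengths)


def which_max(r: RleVector) -> int:
    """Smallest 1-based position attaining the maximum value."""
    if r.total_length == 0:
        raise RangesError("which_max of an empty RleVector")
    run = int(np.argmax(r.run_values))
    return int(r._ends[run] - r.run_lengths[run] + 1)


def extract_range(r: RleVector, start: int, end: int) -> RleVector:
    """The sub-vector over 1-based closed window [start, end]."""
    if start < 1 or end > r.total_length or end < start - 1:
        raise RangesError(
            f"window [{start}, {end}] outside vector of length {r.total_length}")
    if end < start:
        return RleVector(np.empty(0, dtype=r.run_values.dtype),
                         np.empty(0, dtype=np.int64))
    first = int(np.searchsorted(r._ends, start, side="left"))
    last = int(np.searchsorted(r._ends, end, side="left"))
    values = r.run_values[first:last + 1]
    lengths = r.run_lengths[first:last + 1].copy()
    run_starts = r._ends[first:last + 1] - r.run_lengths[first:last + 1] + 1
    lengths[0] -= start - int(run_starts[0])
    lengths[-1] -= int(r._ends[last]) - end
    return RleVector(values, lengths)


class Views:
    """Ranges bound to an RLE subject, for per-range summaries."""

    def __init__(self, subject: RleVector, ranges: IntegerRanges):
        if len(ranges) and (ranges.starts.min() < 1
                            or ranges.ends.max() > subject.total_length):
            raise RangesError("view ranges must lie within the subject")
        self.subject = subject
        self.ranges = ranges

    def __len__(self) -> int:
        return len(self.ranges)

    def __repr__(self) -> str:
        return f"Views({len(self)} views on length-{self.subject.total_length} subject)"


def slice_above(r: RleVector, lower, strict: bool = False) -> Views:
    """Maximal runs of positions with value >= lower (``> lower`` if strict),
    returned as views on ``r``."""
    ok = (r.run_values > lower) if strict else (r.run_values >= lower)
    starts, ends = [], []
    run_start = r._ends - r.run_lengths + 1
    open_start = None
    for i in range(r.n_runs):
        if ok[i]:
            if open_start is None:
                open_start = int(run_start[i])
        elif open_start is not None:
            starts.append(open_start)
            ends.append(int(run_start[i]) - 1)
            open_start = None
    if open_start is not None:
        starts.append(open_start)
        ends.append(r.total_length)
    return Views(r, IntegerRanges(starts, ends))


def view_sums(v: Views) -> np.ndarray:
    """Sum of subject values within each view (0 for zero-width views)."""
    out = np.zeros(len(v), dtype=np.asarray(v.subject.run_values).dtype
                   if v.subject.n_runs else np.int64)
    for i in range(len(v)):
        s, e = int(v.ranges.starts[i]), int(v.ranges.ends[i])
        if e < s:
            continue
        sub = extract_range(v.subject, s, e)
        out[i] = sub.sum()
    return out


def view_maxs(v: Views, empty_sentinel=None) -> np.ndarray:
    """Max of subject values within each view.

    A zero-width view has no maximum: error by default, or substitute
    ``empty_sentinel`` when given.
    """
    out = []
    for i in range(len(v)):
        s, e = int(v.ranges.starts[i]), int(v.ranges.ends[i])
        if e < s:
            if empty_sentinel is None:
                raise RangesError(
                    f"view {i} is zero-width: max over an empty set is undefined "
                    "(pass empty_sentinel= to substitute a value)")
            out.append(empty_sentinel)
        else:
            out.append(extract_range(v.subject, s, e).max())
    return np.asarray(out)
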