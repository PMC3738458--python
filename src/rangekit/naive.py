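"""Naive reference computations on plain integer pairs.

Every function here re-derives a range operation by brute force — per-position
membership sets and all-pairs scans over (start, end) tuples — sharing no code
with the main modules. They exist to validate the optimized implementations
and to attach ground truth to synthetic data sets; they are deliberately slow
and only suitable for small inputs.
"""

from __future__ import annotations

__all__ = [
    "position_set",
    "naive_reduce",
    "naive_disjoin",
    "naive_gaps",
    "naive_set_union",
    "naive_set_intersect",
    "naive_set_setdiff",
    "naive_coverage",
    "naive_find_overlaps",
    "naive_nearest",
    "naive_precede",
    "naive_follow",
    "naive_slice_above",
]

Pairs = list[tuple[int, int]]


def position_set(pairs: Pairs) -> set[int]:
    out: set[int] = set()
    for s, e in pairs:
        for p in range(s, e + 1):
            out.add(p)
    return out


def _set_to_runs(positions: set[int]) -> Pairs:
    runs: Pairs = []
    for p in sorted(positions):
        if runs and p == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], p)
        else:
            runs.append((p, p))
    return runs


def naive_reduce(pairs: Pairs, min_gap: int = 0) -> Pairs:
    runs = _set_to_runs(position_set(pairs))
    if min_gap == 0:
        return runs
    merged: Pairs = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def naive_disjoin(pairs: Pairs) -> Pairs:
    covered = position_set(pairs)
    if not covered:
        return []
    out: Pairs = []
    cur_start = None
    cur_sig = None
    prev = None
    for p in sorted(covered):
        sig = frozenset(i for i, (s, e) in enumerate(pairs) if s <= p <= e)
        if cur_start is None:
            cur_start, cur_sig, prev = p, sig, p
            continue
        if p == prev + 1 and sig == cur_sig:
            prev = p
        else:
            out.append((cur_start, prev))
            cur_start, cur_sig, prev = p, sig, p
    out.append((cur_start, prev))
    return out


def naive_gaps(pairs: Pairs, lo: int, hi: int) -> Pairs:
    covered = position_set(pairs)
    return _set_to_runs({p for p in range(lo, hi + 1) if p not in covered})


def naive_set_union(x: Pairs, y: Pairs) -> Pairs:
    return _set_to_runs(position_set(x) | position_set(y))


def naive_set_intersect(x: Pairs, y: Pairs) -> Pairs:
    return _set_to_runs(position_set(x) & position_set(y))


def naive_set_setdiff(x: Pairs, y: Pairs) -> Pairs:
    return _set_to_runs(position_set(x) - position_set(y))


def naive_coverage(pairs: Pairs, domain_length: int) -> list[int]:
    cov = [0] * domain_length
    for s, e in pairs:
        for p in range(max(s, 1), min(e, domain_length) + 1):
            cov[p - 1] += 1
    return cov


def naive_find_overlaps(query: Pairs, subject: Pairs, mode: str = "any",
                        max_gap: int = 0, min_overlap: int = 1
                        ) -> list[tuple[int, int]]:
    hits = []
    for qi, (qs, qe) in enumerate(query):
        for si, (ss, se) in enumerate(subject):
            ov = min(qe, se) - max(qs, ss) + 1
            if mode == "any":
                ok = ov >= min_overlap
                if not ok and max_gap > 0 and qe >= qs and se >= ss:
                    gap = max(qs, ss) - min(qe, se) - 1
                    ok = 0 <= gap <= max_gap
                if ok:
                    hits.append((qi, si))
            elif mode == "within":
                if ov >= min_overlap and qs >= ss and qe <= se:
                    hits.append((qi, si))
            elif mode == "equal":
                if ov >= min_overlap and qs == ss and qe == se:
                    hits.append((qi, si))
    return sorted(hits)


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, max(a[0], b[0]) - min(a[1], b[1]) - 1)


def naive_nearest(query: Pairs, subject: Pairs) -> list[int]:
    out = []
    for q in query:
        if not subject:
            out.append(-1)
            continue
        dists = [_gap(q, s) for s in subject]
        out.append(dists.index(min(dists)))
    return out


def naive_precede(query: Pairs, subject: Pairs) -> list[int]:
    out = []
    for qs, qe in query:
        best, best_d = -1, None
        for si, (ss, se) in enumerate(subject):
            if ss > qe:
                d = ss - qe - 1
                if best_d is None or d < best_d:
                    best, best_d = si, d
        out.append(best)
    return out


def naive_follow(query: Pairs, subject: Pairs) -> list[int]:
    out = []
    for qs, qe in query:
        best, best_d = -1, None
        for si, (ss, se) in enumerate(subject):
            if se < qs:
                d = qs - se - 1
                if best_d is None or d < best_d:
                    best, best_d = si, d
        out.append(best)
    return out


def naive_slice_above(values: list, lower, strict: bool = False) -> Pairs:
    out: Pairs = []
    for i, v in enumerate(values, start=1):
        ok = v > lower if strict else v >= lower
        if ok:
            if out and out[-1][1] == i - 1:
                out[-1] = (out[-1][0], i)
            else:
                out.append((i, i))
    return out
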