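"""The plain interval algebra against frozen examples and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rangekit as rk
from rangekit import naive
from rangekit.core import RangesError

from conftest import pairs_to_ranges, random_pairs, ranges_to_pairs


# -- construction --------------------------------------------------------------


def test_make_ranges_width_from_endpoints():
    r = rk.make_ranges([106118565], [106118681])
    assert r.widths.tolist() == [117]


def test_make_ranges_empty_and_zero_width():
    assert len(rk.make_ranges([], [])) == 0
    r = rk.make_ranges([5], widths=[0])
    assert (r.starts.tolist(), r.ends.tolist(), r.widths.tolist()) == ([5], [4], [0])


@pytest.mark.parametrize("starts,ends,err", [
    ([1, 2], [5], "length"),
    ([5], [3], "negative width at index 0"),
])
def test_make_ranges_validation(starts, ends, err):
    with pytest.raises(RangesError, match=err):
        rk.make_ranges(starts, ends)


# -- arithmetic -----------------------------------------------------------------


@pytest.mark.parametrize("start,end,amount,expect", [
    (5, 10, 3, (8, 13)),
    (5, 10, 0, (5, 10)),
    (1, 2, -5, (-4, -3)),
])
def test_shift_examples(start, end, amount, expect):
    r = rk.shift(rk.make_ranges([start], [end]), amount)
    assert (r.starts[0], r.ends[0]) == expect


def test_shift_roundtrip_preserves_widths(rng):
    r = pairs_to_ranges(random_pairs(rng, 50))
    amounts = rng.integers(-500, 500, size=50)
    back = rk.shift(rk.shift(r, amounts), -amounts)
    assert back == r
    assert np.array_equal(rk.shift(r, amounts).widths, r.widths)


@pytest.mark.parametrize("rng_in,width,anchor,expect", [
    ((3012936, 3012959), 120, "start", (3012936, 3013055)),
    ((10, 19), 10, "end", (10, 19)),
])
def test_resize_examples(rng_in, width, anchor, expect):
    r = rk.resize(rk.make_ranges([rng_in[0]], [rng_in[1]]), width, anchor=anchor)
    assert (r.starts[0], r.ends[0]) == expect


def test_resize_center_rule():
    # new start = old start + floor((old_w - new_w)/2); midpoint moves <= 0.5
    r = rk.resize(rk.make_ranges([100], [100]), 5000, anchor="center")
    assert r.widths[0] == 5000
    assert r.starts[0] == 100 + (1 - 5000) // 2
    old_mid, new_mid = 100.0, (r.starts[0] + r.ends[0]) / 2
    assert abs(new_mid - old_mid) <= 0.5


def test_resize_fixes_anchor(rng):
    r = pairs_to_ranges(random_pairs(rng, 40))
    assert np.array_equal(rk.resize(r, 7, "start").starts, r.starts)
    assert np.array_equal(rk.resize(r, 7, "end").ends, r.ends)


@pytest.mark.parametrize("start,end,width,side,both,expect", [
    (106118565, 106118681, 200, "start", False, (106118365, 106118564)),
    (10, 20, 0, "end", False, (21, 20)),
    (10, 20, 3, "start", True, (7, 12)),
])
def test_flank_examples(start, end, width, side, both, expect):
    r = rk.flank(rk.make_ranges([start], [end]), width, side=side, both=both)
    assert (r.starts[0], r.ends[0]) == expect


def test_restrict_examples():
    r, kept = rk.restrict(rk.make_ranges([1, 4], [5, 12]), 3, 10)
    assert ranges_to_pairs(r) == [(3, 5), (4, 10)]
    dropped, kept2 = rk.restrict(rk.make_ranges([1], [2]), 5, 9)
    assert len(dropped) == 0 and kept2.tolist() == []


def test_restrict_matches_position_set_oracle(rng):
    pairs = random_pairs(rng, 50, coord_max=200, width_max=40)
    r = pairs_to_ranges(pairs)
    out, kept = rk.restrict(r, 50, 150)
    window = set(range(50, 151))
    expect = [(i, sorted(set(range(s, e + 1)) & window))
              for i, (s, e) in enumerate(pairs)
              if set(range(s, e + 1)) & window]
    assert kept.tolist() == [i for i, _ in expect]
    for (s, e), (_, members) in zip(ranges_to_pairs(out), expect):
        assert list(range(s, e + 1)) == members


@pytest.mark.parametrize("a,b,expect", [
    ((1, 5), (7, 9), 1),
    ((1, 5), (3, 8), 0),
    ((1, 5), (6, 9), 0),
])
def test_distance_examples(a, b, expect):
    d = rk.distance(rk.make_ranges([a[0]], [a[1]]), rk.make_ranges([b[0]], [b[1]]))
    assert d.tolist() == [expect]


def test_range_span():
    kras = rk.make_ranges([106118565, 106119356, 106124887, 106142141, 106143261],
                          [106118681, 106119490, 106125034, 106142541, 106143383])
    assert ranges_to_pairs(rk.range_span(kras)) == [(106118565, 106143383)]
    assert ranges_to_pairs(rk.range_span(rk.make_ranges([5], [5]))) == [(5, 5)]
    assert len(rk.range_span(rk.make_ranges([], []))) == 0


# -- inter-range operations -----------------------------------------------------


def test_reduce_examples_and_index_map():
    r = rk.make_ranges([1, 4, 10], [5, 8, 12])
    merged, imap = rk.reduce_ranges(r)
    assert ranges_to_pairs(merged) == [(1, 8), (10, 12)]
    assert imap.tolist() == [0, 0, 1]
    adjacent, _ = rk.reduce_ranges(rk.make_ranges([1, 6], [5, 9]))
    assert ranges_to_pairs(adjacent) == [(1, 9)]


def test_disjoin_example():
    pieces, covers = rk.disjoin(rk.make_ranges([1, 3], [5, 8]))
    assert ranges_to_pairs(pieces) == [(1, 2), (3, 5), (6, 8)]
    assert [c.tolist() for c in covers] == [[0], [0, 1], [1]]
    ident, _ = rk.disjoin(rk.make_ranges([1], [5]))
    assert ranges_to_pairs(ident) == [(1, 5)]


def test_gaps_examples():
    g = rk.gaps(rk.make_ranges([3, 10], [5, 12]), 1, 15)
    assert ranges_to_pairs(g) == [(1, 2), (6, 9), (13, 15)]
    assert ranges_to_pairs(rk.gaps(rk.make_ranges([], []), 1, 10)) == [(1, 10)]


def test_set_operation_examples():
    a, b = rk.make_ranges([1], [5]), rk.make_ranges([6], [9])
    assert ranges_to_pairs(rk.set_union(a, b)) == [(1, 9)]
    assert len(rk.set_intersect(rk.make_ranges([1], [5]),
                                rk.make_ranges([7], [9]))) == 0
    x = rk.make_ranges([2, 8], [5, 12])
    assert len(rk.set_setdiff(x, x)) == 0


@pytest.mark.parametrize("op,naive_op", [
    (rk.set_union, naive.naive_set_union),
    (rk.set_intersect, naive.naive_set_intersect),
    (rk.set_setdiff, naive.naive_set_setdiff),
])
def test_set_operations_match_position_set_oracle(rng, op, naive_op):
    for _ in range(15):
        xp = random_pairs(rng, 30, coord_max=500, width_max=60,
                          zero_width_frac=0.1)
        yp = random_pairs(rng, 30, coord_max=500, width_max=60)
        got = ranges_to_pairs(op(pairs_to_ranges(xp), pairs_to_ranges(yp)))
        assert got == naive_op(xp, yp)


def test_reduce_disjoin_gaps_match_oracle(rng):
    for _ in range(15):
        pairs = random_pairs(rng, 40, coord_max=800, width_max=80,
                             zero_width_frac=0.1)
        r = pairs_to_ranges(pairs)
        merged, _ = rk.reduce_ranges(r)
        assert ranges_to_pairs(merged) == naive.naive_reduce(pairs)
        min_gap = 5
        merged_g, _ = rk.reduce_ranges(r, min_gap=min_gap)
        assert ranges_to_pairs(merged_g) == naive.naive_reduce(pairs, min_gap)
        pieces, covers = rk.disjoin(r)
        assert ranges_to_pairs(pieces) == naive.naive_disjoin(pairs)
        # covering-input sets are constant along each piece
        for (ps, pe), cov in zip(ranges_to_pairs(pieces), covers):
            for p in (ps, pe):
                members = {i for i, (s, e) in enumerate(pairs) if s <= p <= e}
                assert members == set(cov.tolist())
        assert (ranges_to_pairs(rk.gaps(r, 1, 900))
                == naive.naive_gaps(pairs, 1, 900))


def test_reduce_idempotent_and_gaps_involution(rng):
    pairs = random_pairs(rng, 60, coord_max=1000, width_max=50)
    r = pairs_to_ranges(pairs)
    once, _ = rk.reduce_ranges(r)
    twice, _ = rk.reduce_ranges(once)
    assert once == twice
    # gaps(gaps(r)) within bounds == reduce(r) clipped to bounds
    lo, hi = 1, 1100
    inner = rk.gaps(rk.gaps(r, lo, hi), lo, hi)
    clipped, _ = rk.restrict(once, lo, hi)
    assert inner == clipped


# -- parallel ops -----------------------------------------------------------------


def test_parallel_set_operations():
    assert ranges_to_pairs(rk.p_intersect(rk.make_ranges([1], [5]),
                                          rk.make_ranges([3], [8]))) == [(3, 5)]
    assert ranges_to_pairs(rk.p_gap(rk.make_ranges([1], [5]),
                                    rk.make_ranges([7], [9]))) == [(6, 6)]
    assert ranges_to_pairs(rk.p_union(rk.make_ranges([1], [5]),
                                      rk.make_ranges([6], [9]))) == [(1, 9)]
    with pytest.raises(RangesError, match="index 0"):
        rk.p_union(rk.make_ranges([1], [2]), rk.make_ranges([9], [12]))
    with pytest.raises(RangesError, match="not a single range"):
        rk.p_setdiff(rk.make_ranges([1], [8]), rk.make_ranges([3], [5]))
    trimmed = rk.p_setdiff(rk.make_ranges([1, 4], [8, 9]),
                           rk.make_ranges([5, 1], [10, 5]))
    assert ranges_to_pairs(trimmed) == [(1, 4), (6, 9)]


# -- ordering / extraction / grouping ---------------------------------------------


def test_sort_duplicated_unique():
    r = rk.make_ranges([5, 1, 5], [9, 3, 7])
    assert ranges_to_pairs(rk.sort_ranges(r)) == [(1, 3), (5, 7), (5, 9)]
    d = rk.make_ranges([2, 2], [4, 4])
    assert rk.duplicated(d).tolist() == [False, True]
    assert ranges_to_pairs(rk.unique_ranges(d)) == [(2, 4)]


def test_sort_matches_lexicographic_oracle(rng):
    pairs = random_pairs(rng, 100, coord_max=50, width_max=10)
    got = ranges_to_pairs(rk.sort_ranges(pairs_to_ranges(pairs)))
    assert got == sorted(pairs, key=lambda p: (p[0], p[1] - p[0] + 1))


def test_extraction_and_round_trips():
    r = rk.make_ranges([3, 10], [6, 12], names=["a", "b"],
                       annotations={"score": [1.5, 2.5]})
    assert r.element_sequence(0).tolist() == [3, 4, 5, 6]
    assert len(r[np.zeros(2, dtype=bool)]) == 0
    assert r.rev().rev() == r
    sub = r[[1]]
    assert sub.names.tolist() == ["b"]
    assert sub.annotations.column("score").tolist() == [2.5]
    with pytest.raises(IndexError):
        r[[5]]


def test_split_and_concat():
    r = rk.make_ranges(range(1, 9), range(1, 9))
    grouping = rk.split_ranges(r, ["t1", "t2", "t1", "t3", "t4", "t2", "t3", "t4"])
    assert len(grouping) == 4
    assert grouping.names == ["t1", "t2", "t3", "t4"]
    single = rk.split_ranges(r, ["x"] * 8)
    assert len(single) == 1 and single[0] == r
    back = rk.concat(*list(grouping))
    assert sorted(ranges_to_pairs(back)) == sorted(ranges_to_pairs(r))


# -- hypothesis property: position-set conservation --------------------------------


coord = st.integers(min_value=-10_000, max_value=10_000)
range_pair = st.tuples(coord, st.integers(min_value=0, max_value=100)).map(
    lambda t: (t[0], t[0] + t[1] - 1))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(range_pair, max_size=25), st.lists(range_pair, max_size=25))
def test_position_set_conservation_property(xp, yp):
    x, y = pairs_to_ranges(xp), pairs_to_ranges(yp)
    merged, _ = rk.reduce_ranges(x)
    assert ranges_to_pairs(merged) == naive.naive_reduce(xp)
    pieces, _ = rk.disjoin(x)
    assert ranges_to_pairs(pieces) == naive.naive_disjoin(xp)
    assert merged.position_set() == pieces.position_set() == x.position_set()
    assert ranges_to_pairs(rk.set_union(x, y)) == naive.naive_set_union(xp, yp)
    assert (ranges_to_pairs(rk.set_intersect(x, y))
            == naive.naive_set_intersect(xp, yp))
    assert (ranges_to_pairs(rk.set_setdiff(x, y))
            == naive.naive_set_setdiff(xp, yp))
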