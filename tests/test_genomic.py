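"""Strand-aware genomic operations, sequence registries and grouped lists."""

import numpy as np
import pytest

import rangekit as rk
from rangekit.core import RangesError
from rangekit.genomic import (GenomicRanges, GenomicRangesList, SeqInfo,
                              concat_genomic)

from conftest import pairs_to_ranges, random_pairs


def gr(pairs, seqs=None, strand=None, seq_info=None):
    r = pairs_to_ranges(pairs)
    seqs = seqs or ["chr1"] * len(pairs)
    return GenomicRanges(seqs, r, strand, seq_info)


@pytest.fixture
def random_genomic(rng):
    pairs = random_pairs(rng, 100, coord_max=9000, width_max=100)
    strands = rng.choice(np.array(["+", "-", "*"], dtype=object), size=100)
    seqs = rng.choice(np.array(["chr1", "chr2"], dtype=object), size=100)
    info = SeqInfo(["chr1", "chr2"], {"chr1": 10_000, "chr2": 10_000})
    return GenomicRanges(seqs, pairs_to_ranges(pairs), strands, info)


def test_seqinfo_invariants():
    with pytest.raises(RangesError, match="unique"):
        SeqInfo(["chr1", "chr1"])
    with pytest.raises(RangesError, match="non-positive"):
        SeqInfo(["chr1"], {"chr1": 0})
    si = SeqInfo(["chr2", "chr1"], {"chr1": 100}, genome="test1")
    assert si.seq_names == ["chr2", "chr1"]  # insertion order preserved
    assert si.length_of("chr2") is None


def test_granges_validation():
    with pytest.raises(RangesError, match="absent from SeqInfo"):
        GenomicRanges(["chrX"], rk.make_ranges([1], [5]), None,
                      SeqInfo(["chr1"]))
    with pytest.raises(RangesError, match="strand"):
        GenomicRanges(["chr1"], rk.make_ranges([1], [5]), ["?"])


def test_genomic_resize_strand_semantics():
    plus = gr([(3012936, 3012959)], seqs=["chr10"], strand=["+"])
    out = rk.genomic_resize(plus, 120, anchor="start")
    assert (out.starts[0], out.ends[0]) == (3012936, 3013055)
    minus = gr([(3012936, 3012959)], seqs=["chr10"], strand=["-"])
    out_m = rk.genomic_resize(minus, 120, anchor="start")
    assert (out_m.starts[0], out_m.ends[0]) == (3012840, 3012959)
    star = gr([(3012936, 3012959)], seqs=["chr10"], strand=["*"])
    out_s = rk.genomic_resize(star, 120, anchor="start")
    assert (out_s.starts[0], out_s.ends[0]) == (3012936, 3013055)


def test_genomic_flank_strand_semantics():
    exon1 = gr([(106118565, 106118681)], seqs=["chr13"], strand=["+"])
    up = rk.genomic_flank(exon1, 200, side="start")
    assert (up.starts[0], up.ends[0]) == (106118365, 106118564)
    exon1_m = gr([(106118565, 106118681)], seqs=["chr13"], strand=["-"])
    up_m = rk.genomic_flank(exon1_m, 200, side="start")
    assert (up_m.starts[0], up_m.ends[0]) == (106118682, 106118881)


def test_strand_flip_symmetry(random_genomic):
    g = random_genomic
    for op, kwargs, swapped in [
        (rk.genomic_resize, {"width": 37, "anchor": "start"},
         {"width": 37, "anchor": "end"}),
        (rk.genomic_resize, {"width": 37, "anchor": "center"},
         {"width": 37, "anchor": "center"}),
        (rk.genomic_flank, {"width": 15, "side": "start"},
         {"width": 15, "side": "end"}),
    ]:
        flipped_then_op = op(rk.flip_strand(g), **kwargs)
        op_then_flipped = rk.flip_strand(op(g, **swapped))
        # '*' behaves as '+' on both paths only when the op itself is
        # symmetric; restrict the check to stranded elements
        stranded = np.nonzero(g.strand != "*")[0]
        assert flipped_then_op[stranded] == op_then_flipped[stranded]


def test_overlaps_respect_sequence_and_strand():
    info = SeqInfo(["chr1", "chr2"])
    a = gr([(1, 10)], seqs=["chr1"], strand=["+"], seq_info=info)
    b = gr([(1, 10)], seqs=["chr2"], strand=["+"], seq_info=info)
    assert len(rk.genomic_find_overlaps(a, b)) == 0
    c = gr([(5, 20)], seqs=["chr1"], strand=["-"], seq_info=info)
    assert len(rk.genomic_find_overlaps(a, c)) == 0
    assert rk.genomic_find_overlaps(a, c, ignore_strand=True).pairs() == [(0, 0)]
    star = gr([(5, 20)], seqs=["chr1"], strand=["*"], seq_info=info)
    assert rk.genomic_find_overlaps(a, star).pairs() == [(0, 0)]


def test_no_cross_sequence_hits_on_identical_coordinates(rng):
    # adversarial: same coordinates on different chromosomes
    pairs = random_pairs(rng, 50, coord_max=500, width_max=40)
    info = SeqInfo(["chr1", "chr2"])
    a = gr(pairs, seqs=["chr1"] * 50, seq_info=info)
    b = gr(pairs, seqs=["chr2"] * 50, seq_info=info)
    assert len(rk.genomic_find_overlaps(a, b, ignore_strand=True)) == 0


def test_cross_build_operations_error():
    a = gr([(1, 10)], seq_info=SeqInfo(["chr1"], genome="hg19"))
    b = gr([(1, 10)], seq_info=SeqInfo(["chr1"], genome="mm9"))
    with pytest.raises(RangesError, match="genome builds"):
        rk.genomic_find_overlaps(a, b)


def test_element_level_list_overlap():
    info = SeqInfo(["chr1"])
    q_flat = gr([(1, 5), (20, 25)], seq_info=info)
    query = GenomicRangesList(q_flat, [2], names=["q1"])
    s_flat = gr([(22, 30)], seq_info=info)
    subject = GenomicRangesList(s_flat, [1], names=["s1"])
    hits = rk.genomic_find_overlaps(query, subject, ignore_strand=True)
    assert hits.pairs() == [(0, 0)]  # one element-level hit, deduplicated


def test_list_overlap_matches_flatten_project_dedup_oracle(rng):
    info = SeqInfo(["chr1"])
    pairs_q = random_pairs(rng, 60, coord_max=3000, width_max=60)
    pairs_s = random_pairs(rng, 60, coord_max=3000, width_max=60)
    fq = gr(pairs_q, seqs=["chr1"] * 60, seq_info=info)
    fs = gr(pairs_s, seqs=["chr1"] * 60, seq_info=info)
    Lq = rk.group_genomic(fq, [f"g{i % 12}" for i in range(60)])
    Ls = rk.group_genomic(fs, [f"h{i % 15}" for i in range(60)])
    got = rk.genomic_find_overlaps(Lq, Ls, ignore_strand=True).pairs()
    flat_hits = rk.genomic_find_overlaps(Lq.flat, Ls.flat,
                                         ignore_strand=True).pairs()
    gq, gs = Lq.partition.group_of(), Ls.partition.group_of()
    expect = sorted({(int(gq[a]), int(gs[b])) for a, b in flat_hits})
    assert got == expect


def test_keep_and_rename_seqlevels():
    info = SeqInfo(["chrXIII", "chrXIV"], {"chrXIII": 924431, "chrXIV": 784333})
    g = gr([(100, 200), (300, 400)], seqs=["chrXIII", "chrXIV"], seq_info=info)
    kept = rk.keep_seqlevels(g, ["chrXIII"])
    assert len(kept) == 1 and kept.seq_info.seq_names == ["chrXIII"]
    renamed = rk.rename_seqlevels(kept, {"chrXIII": "Scchr13"})
    assert renamed.seq_names.tolist() == ["Scchr13"]
    assert renamed.seq_info.seq_lengths == {"Scchr13": 924431}
    assert rk.keep_seqlevels(g, ["chrXIII", "chrXIV"]) == g
    with pytest.raises(RangesError):
        rk.keep_seqlevels(g, ["chrII"])
    # keep-then-rename commutes with rename-restricted-to-kept
    a = rk.rename_seqlevels(rk.keep_seqlevels(g, ["chrXIII"]),
                            {"chrXIII": "s13"})
    b = rk.keep_seqlevels(rk.rename_seqlevels(g, {"chrXIII": "s13"}), ["s13"])
    assert a == b and a.seq_info == b.seq_info


def test_grouping_and_extraction(random_genomic):
    g = random_genomic
    factor = [f"t{i % 7}" for i in range(len(g))]
    L = rk.group_genomic(g, factor)
    assert len(L) == 7
    member = rk.list_extract(L, "t3")
    assert len(member) == sum(1 for f in factor if f == "t3")
    back = concat_genomic(*list(L))
    assert sorted(zip(back.starts.tolist(), back.ends.tolist())) \
        == sorted(zip(g.starts.tolist(), g.ends.tolist()))
    single = L["t0"]
    one = rk.group_genomic(single, ["x"] * len(single))
    assert one["x"] == single
    with pytest.raises(KeyError):
        L["missing"]


def test_genomic_coverage_per_sequence(random_genomic):
    g = random_genomic
    cov = rk.genomic_coverage(g)
    total = 0
    for seq in ["chr1", "chr2"]:
        idx = np.nonzero(g.seq_names == seq)[0]
        expect = rk.coverage(g.ranges[idx], 10_000)
        assert cov[seq] == expect
        total += cov[seq].sum()
    clipped = np.minimum(g.ends, 10_000) - np.maximum(g.starts, 1) + 1
    assert total == np.maximum(clipped, 0).sum()


def test_genomic_coverage_empty_input_gives_zero_vectors():
    info = SeqInfo(["chr1", "chr2"], {"chr1": 50, "chr2": 70})
    g = GenomicRanges([], rk.make_ranges([], []), None, info)
    cov = rk.genomic_coverage(g)
    assert cov["chr1"].total_length == 50 and cov["chr1"].sum() == 0
    assert cov["chr2"].total_length == 70


def test_trim_and_out_of_bounds():
    info = SeqInfo(["chr1"], {"chr1": 100})
    g = gr([(90, 130)], seq_info=info)
    assert g.out_of_bounds().tolist() == [True]
    t = rk.trim(g)
    assert (t.starts[0], t.ends[0]) == (90, 100)


def test_list_single_backing_store_invariant(random_genomic):
    L = rk.group_genomic(random_genomic, [f"g{i % 5}" for i in range(100)])
    rebuilt = concat_genomic(*list(L))
    assert rebuilt == L.flat
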