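"""Element-level read counting and the feature x sample container."""

import numpy as np
import pytest

import rangekit as rk
from rangekit.core import AnnotationTable, RangesError
from rangekit.genomic import GenomicRanges, SeqInfo, group_genomic
from rangekit.summarize import (SummarizedExperiment, count_features,
                                read_counts_tsv, se_subset,
                                summarize_overlaps, write_counts_tsv)

from conftest import pairs_to_ranges, random_pairs


INFO = SeqInfo(["chr1"], {"chr1": 100_000})


def glist(pair_groups, strands=None, names=None):
    pairs = [p for grp in pair_groups for p in grp]
    n = len(pairs)
    strands = strands or ["+"] * n
    flat = GenomicRanges(["chr1"] * n, pairs_to_ranges(pairs), strands, INFO)
    factor = [i for i, grp in enumerate(pair_groups) for _ in grp]
    L = group_genomic(flat, factor)
    return L


def test_element_level_counting():
    # a 2-exon transcript; read overlaps exon 2 only -> one count
    features = glist([[(1, 100), (500, 600)]])
    reads = glist([[(550, 560)]])
    assert count_features(features, reads, ignore_strand=True).tolist() == [1]


def test_strand_flag_controls_counting():
    features = glist([[(1, 100)]])
    reads = glist([[(50, 60)]], strands=["-"])
    assert count_features(features, reads, ignore_strand=False).tolist() == [0]
    assert count_features(features, reads, ignore_strand=True).tolist() == [1]


def test_count_features_matches_flatten_project_oracle(rng):
    fp = random_pairs(rng, 60, coord_max=20_000, width_max=400)
    rp = random_pairs(rng, 120, coord_max=20_000, width_max=50)
    features = glist([fp[i:i + 3] for i in range(0, 60, 3)])
    reads = glist([[p] for p in rp])
    got = count_features(features, reads, ignore_strand=True)
    # oracle: all-pairs on flat ranges, projected to (feature, read), dedup
    hits = set()
    ffl, rfl = features.flat, reads.flat
    fg = features.partition.group_of()
    for fi in range(len(ffl)):
        for ri in range(len(rfl)):
            if (ffl.starts[fi] <= rfl.ends[ri]
                    and rfl.starts[ri] <= ffl.ends[fi]):
                hits.add((int(fg[fi]), ri))
    expect = np.bincount([f for f, _ in hits], minlength=len(features))
    assert got.tolist() == expect.tolist()


def test_multihit_reads_discarded_in_union_mode():
    features = glist([[(1, 100)], [(50, 200)]])
    read_both = glist([[(60, 70)]])  # overlaps both features
    se = summarize_overlaps(features, [read_both], ignore_strand=True)
    assert se.assay("counts").ravel().tolist() == [0, 0]
    disjoint = glist([[(1, 100)], [(500, 600)]])
    one_each = glist([[(10, 20)], [(510, 520)]])
    se2 = summarize_overlaps(disjoint, [one_each], ignore_strand=True)
    assert se2.assay("counts").ravel().tolist() == [1, 1]


def test_read_hitting_one_feature_twice_is_not_a_multihit():
    # spliced read touching both exons of the same transcript
    features = glist([[(1, 100), (500, 600)]])
    read = glist([[(90, 100), (500, 510)]])
    se = summarize_overlaps(features, [read], ignore_strand=True)
    assert se.assay("counts").ravel().tolist() == [1]


def test_count_all_mode_matches_count_features(rng):
    fp = random_pairs(rng, 30, coord_max=10_000, width_max=300)
    rp = random_pairs(rng, 80, coord_max=10_000, width_max=40)
    features = glist([fp[i:i + 2] for i in range(0, 30, 2)])
    reads = glist([[p] for p in rp])
    se = summarize_overlaps(features, {"s1": reads}, mode="count_all",
                            ignore_strand=True)
    assert se.assay("counts")[:, 0].tolist() \
        == count_features(features, reads, ignore_strand=True).tolist()
    # union mode never counts a read twice
    se_u = summarize_overlaps(features, {"s1": reads}, ignore_strand=True)
    assert se_u.assay("counts")[:, 0].sum() <= len(reads)


def test_counts_invariant_to_feature_order(rng):
    fp = random_pairs(rng, 20, coord_max=5000, width_max=200)
    rp = random_pairs(rng, 50, coord_max=5000, width_max=40)
    features = glist([[p] for p in fp])
    reads = glist([[p] for p in rp])
    fwd = summarize_overlaps(features, [reads], ignore_strand=True)
    rev_features = glist([[p] for p in fp[::-1]])
    rev = summarize_overlaps(rev_features, [reads], ignore_strand=True)
    assert fwd.assay("counts")[:, 0].tolist() \
        == rev.assay("counts")[::-1, 0].tolist()


def test_empty_feature_set_rejected():
    reads = glist([[(1, 10)]])
    with pytest.raises(RangesError, match="non-empty feature"):
        summarize_overlaps(glist([[]]), [reads], ignore_strand=True)


def test_seqinfo_mismatch_guides_to_rename():
    features = glist([[(1, 100)]])
    other = SeqInfo(["chrI"], {"chrI": 1000})
    reads_flat = GenomicRanges(["chrI"], pairs_to_ranges([(10, 20)]),
                               ["+"], other)
    reads = group_genomic(reads_flat, ["r1"])
    with pytest.raises(RangesError, match="rename_seqlevels"):
        count_features(features, reads)


def test_se_container_invariants_and_subset():
    counts = np.arange(12).reshape(4, 3)
    features = glist([[(i * 100 + 1, i * 100 + 50)] for i in range(4)])
    se = SummarizedExperiment(
        {"counts": counts}, row_ranges=features,
        column_data=AnnotationTable({"sample": ["a", "b", "c"]}))
    assert se.shape == (4, 3)
    full = se_subset(se)
    assert np.array_equal(full.assay("counts"), counts)
    one = se_subset(se, [2], [1])
    assert one.shape == (1, 1) and one.assay("counts")[0, 0] == 7
    assert one.column_data.column("sample").tolist() == ["b"]
    # subsetting composes
    two_step = se_subset(se_subset(se, [1, 2, 3]), [1], [0, 2])
    direct = se_subset(se, [2], [0, 2])
    assert np.array_equal(two_step.assay("counts"), direct.assay("counts"))
    with pytest.raises(IndexError):
        se_subset(se, [9])
    with pytest.raises(RangesError, match="shape"):
        SummarizedExperiment({"a": np.zeros((2, 2)), "b": np.zeros((3, 2))})


def test_counts_tsv_round_trip(tmp_path):
    features = glist([[(1, 100)], [(500, 600)]])
    reads = glist([[(10, 20)], [(510, 520)]])
    se = summarize_overlaps(features, {"wt1": reads, "wt2": reads},
                            ignore_strand=True)
    path = tmp_path / "counts.tsv"
    write_counts_tsv(se, path, feature_ids=["tx1", "tx2"])
    back = read_counts_tsv(path)
    assert np.array_equal(back.assay("counts"), se.assay("counts"))
    assert back.column_data.column("sample").tolist() == ["wt1", "wt2"]
    assert back.metadata["feature_ids"] == ["tx1", "tx2"]
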