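"""Multi-sample overlap counting and the feature x sample container.

The end point of most counting workflows is a matrix whose rows are genomic
features (transcripts, exons, peaks) and whose columns are samples, bundled
with the feature ranges and per-sample metadata so the three never drift
apart. Counting is element-level: a read (itself possibly a gapped,
multi-segment feature) hits a transcript once no matter how many of its
segments touch how many exons. The ``union_discard_multihit`` mode
additionally discards reads hitting more than one feature, the conservative
choice for expression counting; ``count_all`` credits every feature a read
touches.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnnotationTable, RangesError
from .genomic import GenomicRanges, GenomicRangesList, genomic_find_overlaps

__all__ = [
    "SummarizedExperiment",
    "count_features",
    "summarize_overlaps",
    "se_subset",
    "write_counts_tsv",
    "read_counts_tsv",
]


class SummarizedExperiment:
    """Named assay matrices + row ranges + sample table + metadata."""

    def __init__(self, assays: Mapping[str, np.ndarray],
                 row_ranges: GenomicRanges | GenomicRangesList | None = None,
                 column_data: AnnotationTable | None = None,
                 metadata: dict | None = None):
        self.assays = {k: np.asarray(v) for k, v in assays.items()}
        if not self.assays:
            raise RangesError("at least one assay required")
        shapes = {a.shape for a in self.assays.values()}
        if len(shapes) != 1 or len(next(iter(shapes))) != 2:
            raise RangesError("all assays must share one (features, samples) shape")
        self.n_features, self.n_samples = next(iter(shapes))
        if row_ranges is not None and len(row_ranges) != self.n_features:
            raise RangesError("row_ranges length != number of assay rows")
        self.row_ranges = row_ranges
        if column_data is None:
            column_data = AnnotationTable(n_rows=self.n_samples)
        elif column_data.n_rows != self.n_samples:
            raise RangesError("column_data rows != number of assay columns")
        self.column_data = column_data
        self.metadata = dict(metadata or {})

    def assay(self, name: str = "counts") -> np.ndarray:
        if name not in self.assays:
            raise KeyError(f"no assay {name!r}")
        return self.assays[name]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_features, self.n_samples)

    def __repr__(self) -> str:
        return (f"SummarizedExperiment({self.n_features} features x "
                f"{self.n_samples} samples; assays={list(self.assays)})")


def _check_counting_inputs(features, reads):
    f_flat = features.flat if isinstance(features, GenomicRangesList) else features
    r_flat = reads.flat if isinstance(reads, GenomicRangesList) else reads
    fg, rg = f_flat.seq_info.genome, r_flat.seq_info.genome
    if fg and rg and fg != rg:
        raise RangesError(
            f"features ({fg!r}) and reads ({rg!r}) are on different genome "
            "builds; use rename_seqlevels/keep_seqlevels to reconcile them")
    f_names = set(f_flat.seq_info.seq_names)
    r_names = set(r_flat.seq_info.seq_names)
    if f_names and r_names and not (f_names & r_names):
        raise RangesError(
            "features and reads share no sequence names; use "
            "rename_seqlevels/keep_seqlevels to reconcile them")


def count_features(features: GenomicRangesList, reads,
                   ignore_strand: bool = False,
                   min_overlap: int = 1) -> np.ndarray:
    """Per-feature count of reads with an element-level overlap.

    A read overlapping k features contributes to all k.
    """
    _check_counting_inputs(features, reads)
    hits = genomic_find_overlaps(features, reads, mode="any",
                                 min_overlap=min_overlap,
                                 ignore_strand=ignore_strand)
    n = len(features)
    return np.bincount(hits.query_index, minlength=n).astype(np.int64)


def summarize_overlaps(features: GenomicRangesList,
                       samples: Mapping[str, GenomicRangesList] |
                       Sequence[GenomicRangesList],
                       mode: str = "union_discard_multihit",
                       ignore_strand: bool = False) -> SummarizedExperiment:
    """Count reads per feature over multiple samples.

    ``union_discard_multihit`` drops any read hitting more than one feature
    before counting (a read hitting one feature several times — e.g. two
    exons of one transcript — is a single hit, not a multi-hit);
    ``count_all`` matches :func:`count_features` per sample.
    """
    if mode not in ("union_discard_multihit", "count_all"):
        raise RangesError(f"unknown counting mode {mode!r}")
    if len(features) == 0:
        raise RangesError("summarize_overlaps needs a non-empty feature set")
    if isinstance(samples, Mapping):
        sample_names = list(samples.keys())
        sample_list = list(samples.values())
    else:
        sample_list = list(samples)
        sample_names = [f"sample{i + 1}" for i in range(len(sample_list))]
    if not sample_list:
        raise RangesError("summarize_overlaps needs at least one sample")

    n = len(features)
    counts = np.zeros((n, len(sample_list)), dtype=np.int64)
    for j, reads in enumerate(sample_list):
        _check_counting_inputs(features, reads)
        hits = genomic_find_overlaps(features, reads, mode="any",
                                     ignore_strand=ignore_strand)
        if mode == "count_all":
            counts[:, j] = np.bincount(hits.query_index, minlength=n)
        else:
            n_reads = (len(reads) if isinstance(reads, GenomicRangesList)
                       else len(reads))
            per_read = np.bincount(hits.subject_index, minlength=n_reads)
            uniq = per_read[hits.subject_index] == 1
            counts[:, j] = np.bincount(hits.query_index[uniq], minlength=n)
    column_data = AnnotationTable({"sample": sample_names})
    row_ranges = features
    return SummarizedExperiment({"counts": counts}, row_ranges=row_ranges,
                                column_data=column_data,
                                metadata={"mode": mode,
                                          "ignore_strand": ignore_strand})


def se_subset(se: SummarizedExperiment, feature_index=None,
              sample_index=None) -> SummarizedExperiment:
    """Subset assays, row ranges and sample table coherently."""
    fi = (np.arange(se.n_features) if feature_index is None
          else np.asarray(feature_index))
    si = (np.arange(se.n_samples) if sample_index is None
          else np.asarray(sample_index))
    if fi.dtype == bool:
        fi = np.nonzero(fi)[0]
    if si.dtype == bool:
        si = np.nonzero(si)[0]
    if fi.size and (fi.min() < 0 or fi.max() >= se.n_features):
        raise IndexError("feature index out of bounds")
    if si.size and (si.min() < 0 or si.max() >= se.n_samples):
        raise IndexError("sample index out of bounds")
    assays = {k: a[np.ix_(fi, si)] for k, a in se.assays.items()}
    row_ranges = None
    if se.row_ranges is not None:
        if isinstance(se.row_ranges, GenomicRangesList):
            groups = [se.row_ranges[int(i)] for i in fi]
            names = ([se.row_ranges.names[int(i)] for i in fi]
                     if se.row_ranges.names is not None else None)
            row_ranges = (GenomicRangesList.from_groups(groups, names=names)
                          if groups else None)
        else:
            row_ranges = se.row_ranges[fi]
    return SummarizedExperiment(assays, row_ranges=row_ranges,
                                column_data=se.column_data.subset(si),
                                metadata=se.metadata)


def write_counts_tsv(se: SummarizedExperiment, path, assay: str = "counts",
                     feature_ids: Sequence[str] | None = None):
    """Counts matrix as TSV: feature ids as row names, sample ids as header."""
    if feature_ids is None:
        if (isinstance(se.row_ranges, GenomicRangesList)
                and se.row_ranges.names is not None):
            feature_ids = se.row_ranges.names
        else:
            feature_ids = [f"feature{i + 1}" for i in range(se.n_features)]
    if "sample" in se.column_data.column_names:
        sample_ids = [str(s) for s in se.column_data.column("sample")]
    else:
        sample_ids = [f"sample{j + 1}" for j in range(se.n_samples)]
    df = pd.DataFrame(se.assay(assay), index=list(feature_ids),
                      columns=sample_ids)
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(path) -> SummarizedExperiment:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SummarizedExperiment(
        {"counts": df.to_numpy(dtype=np.int64)},
        column_data=AnnotationTable({"sample": [str(c) for c in df.columns]}),
        metadata={"feature_ids": [str(i) for i in df.index]})
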