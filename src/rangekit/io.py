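"""Readers and writers for BED, bedGraph, GFF3/GTF, SAM text and TSV tables.

All coordinate-basis arithmetic lives here and nowhere else. Internally every
range is 1-based and closed; BED and bedGraph are 0-based half-open (so a BED
start is incremented on import and the end copied verbatim), while GFF3/GTF
coordinates are already 1-based closed and pass through untouched. A
zero-length BED feature (start == end) maps to an internal zero-width range —
an insertion point — rather than an error.

Readers stream line-wise and report the first problem with file:line context.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AnnotationTable, IntegerRanges, RangesError
from .genomic import GenomicRanges, SeqInfo
from .rle import RleVector

__all__ = [
    "read_bed",
    "write_bed",
    "read_gff",
    "write_gff",
    "read_bedgraph",
    "write_bedgraph",
    "read_ranges_tsv",
    "write_ranges_tsv",
    "read_seqinfo_tsv",
    "read_sam",
]


class FormatError(RangesError):
    """A malformed record, reported with file:line context."""


def _open_lines(path):
    if hasattr(path, "read"):
        return path, "<stream>"
    return open(path, "rt"), str(path)


# -- BED ---------------------------------------------------------------------


def read_bed(path, seq_info: SeqInfo | None = None) -> GenomicRanges:
    """Read BED3/6; 0-based half-open -> 1-based closed (start+1, end)."""
    fh, label = _open_lines(path)
    seqs, starts, ends, names, scores, strands = [], [], [], [], [], []
    has_name = has_score = has_strand = False
    with fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{label}:{ln}: BED needs >= 3 columns")
            try:
                s0, e0 = int(f[1]), int(f[2])
            except ValueError:
                raise FormatError(f"{label}:{ln}: non-numeric BED coordinates")
            if e0 < s0:
                raise FormatError(f"{label}:{ln}: BED end < start")
            seqs.append(f[0])
            starts.append(s0 + 1)
            ends.append(e0)
            if len(f) >= 4 and f[3] != ".":
                has_name = True
                names.append(f[3])
            else:
                names.append(None)
            if len(f) >= 5:
                has_score = True
                scores.append(float(f[4]))
            else:
                scores.append(np.nan)
            if len(f) >= 6:
                if f[5] not in ("+", "-", "."):
                    raise FormatError(f"{label}:{ln}: malformed strand {f[5]!r}")
                has_strand = True
                strands.append("*" if f[5] == "." else f[5])
            else:
                strands.append("*")
    ann = AnnotationTable(n_rows=len(seqs))
    if has_score:
        ann = ann.with_column("score", scores)
    ranges = IntegerRanges(starts, ends,
                           names=names if has_name else None,
                           annotations=ann)
    return GenomicRanges(seqs, ranges, strands if has_strand else None, seq_info)


def write_bed(g: GenomicRanges, path):
    """Write BED; 1-based closed -> 0-based half-open (start-1, end).

    Emits only as many columns as the data carries: BED3 for bare ranges,
    up to BED6 when names, scores or strands are present.
    """
    has_score = "score" in g.annotations.column_names
    has_name = g.names is not None
    has_strand = bool(len(g)) and (g.strand != "*").any()
    n_cols = 6 if has_strand else 5 if has_score else 4 if has_name else 3
    with open(path, "wt") as fh:
        for i in range(len(g)):
            cols = [str(g.seq_names[i]), str(g.starts[i] - 1), str(g.ends[i])]
            if n_cols >= 4:
                cols.append(str(g.names[i]) if has_name
                            and g.names[i] is not None else ".")
            if n_cols >= 5:
                cols.append(repr(float(g.annotations.column("score")[i]))
                            if has_score else "0")
            if n_cols >= 6:
                strand = str(g.strand[i])
                cols.append("." if strand == "*" else strand)
            fh.write("\t".join(cols) + "\n")


# -- GFF3 / GTF ---------------------------------------------------------------


def _parse_attributes(text: str, dialect: str, label: str, ln: int) -> dict:
    attrs: dict[str, str] = {}
    text = text.strip()
    if text in (".", ""):
        return attrs
    if dialect == "gff3":
        for chunk in text.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "=" not in chunk:
                raise FormatError(
                    f"{label}:{ln}: unparseable GFF3 attribute {chunk!r}")
            k, v = chunk.split("=", 1)
            attrs[k.strip()] = v.strip()
    else:  # gtf: key "value"; pairs, unquoted numerics tolerated
        for chunk in text.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            parts = chunk.split(None, 1)
            if len(parts) != 2:
                raise FormatError(
                    f"{label}:{ln}: unparseable GTF attribute {chunk!r}")
            k, v = parts
            attrs[k] = v.strip().strip('"')
    return attrs


def read_gff(path, dialect: str = "gtf",
             seq_info: SeqInfo | None = None) -> GenomicRanges:
    """Read GFF3/GTF feature rows (1-based closed, verbatim).

    Columns source/feature/score/frame plus every attribute key become
    annotation columns (missing attributes are None).
    """
    if dialect not in ("gff3", "gtf"):
        raise RangesError(f"unknown GFF dialect {dialect!r}")
    fh, label = _open_lines(path)
    rows = []
    with fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(
                    f"{label}:{ln}: expected 9 tab-separated columns, got {len(f)}")
            try:
                start, end = int(f[3]), int(f[4])
            except ValueError:
                raise FormatError(f"{label}:{ln}: non-numeric coordinates")
            if end < start - 1:
                raise FormatError(f"{label}:{ln}: end < start - 1")
            if f[6] not in ("+", "-", ".", "?"):
                raise FormatError(f"{label}:{ln}: malformed strand {f[6]!r}")
            rec = {
                "seq_name": f[0], "source": f[1], "feature": f[2],
                "start": start, "end": end,
                "score": None if f[5] == "." else float(f[5]),
                "strand": "*" if f[6] in (".", "?") else f[6],
                "frame": f[7],
            }
            rec.update(_parse_attributes(f[8], dialect, label, ln))
            rows.append(rec)
    if not rows:
        ranges = IntegerRanges([], [], annotations=AnnotationTable(
            {"source": [], "feature": [], "score": [], "frame": []}))
        return GenomicRanges([], ranges, None, seq_info)
    df = pd.DataFrame(rows)
    fixed = ["seq_name", "start", "end", "strand"]
    ann_cols = [c for c in df.columns if c not in fixed]
    ann = AnnotationTable(df[ann_cols].astype(object).where(df[ann_cols].notna(),
                                                            None))
    ranges = IntegerRanges(df["start"].to_numpy(), df["end"].to_numpy(),
                           annotations=ann)
    return GenomicRanges(df["seq_name"].tolist(), ranges,
                         df["strand"].tolist(), seq_info)


def write_gff(g: GenomicRanges, path, dialect: str = "gtf"):
    """Write feature rows; annotation columns beyond the fixed GFF fields are
    emitted as attributes in sorted key order."""
    if dialect not in ("gff3", "gtf"):
        raise RangesError(f"unknown GFF dialect {dialect!r}")
    fixed = ("source", "feature", "score", "frame")
    ann = g.annotations
    attr_cols = [c for c in ann.column_names if c not in fixed]
    with open(path, "wt") as fh:
        for i in range(len(g)):
            def col(name, default):
                if name in ann.column_names:
                    v = ann.column(name)[i]
                    return default if v is None or (isinstance(v, float)
                                                    and np.isnan(v)) else v
                return default
            score = col("score", ".")
            strand = str(g.strand[i])
            parts = []
            for c in attr_cols:
                v = ann.column(c)[i]
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    continue
                if dialect == "gff3":
                    parts.append(f"{c}={v}")
                else:
                    parts.append(f'{c} "{v}"')
            attrs = (";".join(parts) if dialect == "gff3"
                     else "; ".join(parts) + (";" if parts else "")) or "."
            fh.write("\t".join([
                str(g.seq_names[i]), str(col("source", ".")),
                str(col("feature", "feature")), str(g.starts[i]),
                str(g.ends[i]),
                "." if score == "." else repr(float(score)),
                "." if strand == "*" else strand,
                str(col("frame", ".")), attrs]) + "\n")


# -- bedGraph -----------------------------------------------------------------


def write_bedgraph(rle_map: Mapping[str, RleVector], path,
                   skip_zero: bool = False):
    """One row per run, 0-based half-open, value column from the run value."""
    with open(path, "wt") as fh:
        for seq, r in rle_map.items():
            pos = 0
            for v, n in zip(r.run_values, r.run_lengths):
                if not (skip_zero and v == 0):
                    fh.write(f"{seq}\t{pos}\t{pos + int(n)}\t{v}\n")
                pos += int(n)


def read_bedgraph(path) -> dict[str, RleVector]:
    """Reconstruct per-sequence RLE vectors from contiguous bedGraph rows."""
    fh, label = _open_lines(path)
    per_seq: dict[str, tuple[list, list]] = {}
    cursor: dict[str, int] = {}
    with fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise FormatError(f"{label}:{ln}: bedGraph needs 4 columns")
            seq, s0, e0, val = f[0], int(f[1]), int(f[2]), float(f[3])
            if e0 <= s0:
                raise FormatError(f"{label}:{ln}: empty bedGraph run")
            values, lengths = per_seq.setdefault(seq, ([], []))
            at = cursor.get(seq, 0)
            if s0 < at:
                raise FormatError(f"{label}:{ln}: overlapping bedGraph runs")
            if s0 > at:  # gap -> implicit zero run
                values.append(0.0)
                lengths.append(s0 - at)
            values.append(val)
            lengths.append(e0 - s0)
            cursor[seq] = e0
    out = {}
    for seq, (values, lengths) in per_seq.items():
        arr = np.asarray(values)
        if np.all(arr == np.round(arr)):
            arr = arr.astype(np.int64)
        out[seq] = RleVector(arr, lengths)
    return out


# -- TSV range tables ---------------------------------------------------------


def write_ranges_tsv(g: GenomicRanges, path):
    """Columns seq_name, start, end, strand, name, then annotation columns."""
    df = pd.DataFrame({
        "seq_name": g.seq_names,
        "start": g.starts,
        "end": g.ends,
        "strand": g.strand,
    })
    if g.names is not None:
        df["name"] = g.names
    ann = g.annotations.to_frame()
    for c in ann.columns:
        df[c] = ann[c].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def read_ranges_tsv(path, seq_info: SeqInfo | None = None) -> GenomicRanges:
    df = pd.read_csv(path, sep="\t", dtype={"seq_name": str})
    for needed in ("seq_name", "start", "end"):
        if needed not in df.columns:
            raise FormatError(f"{path}: TSV range table missing {needed!r}")
    strand = df["strand"].tolist() if "strand" in df.columns else None
    names = df["name"].tolist() if "name" in df.columns else None
    ann_cols = [c for c in df.columns
                if c not in ("seq_name", "start", "end", "strand", "name")]
    ann = AnnotationTable(df[ann_cols]) if ann_cols else None
    ranges = IntegerRanges(df["start"].to_numpy(), df["end"].to_numpy(),
                           names=names, annotations=ann)
    return GenomicRanges(df["seq_name"].tolist(), ranges, strand, seq_info)


def read_seqinfo_tsv(path) -> SeqInfo:
    """Columns: seq_name, length (optional), genome (optional, constant)."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_name": str})
    if "seq_name" not in df.columns:
        raise FormatError(f"{path}: seqinfo TSV missing 'seq_name'")
    lengths = None
    if "length" in df.columns:
        lengths = {str(n): int(L) for n, L in zip(df["seq_name"], df["length"])
                   if pd.notna(L)}
    genome = None
    if "genome" in df.columns and len(df):
        genome = str(df["genome"].iloc[0])
    return SeqInfo(df["seq_name"].tolist(), lengths, genome=genome)


def read_sam(path, primary_only: bool = False):
    """Adapter to :func:`rangekit.alignments.read_alignments`."""
    from .alignments import read_alignments

    return read_alignments(path, primary_only=primary_only)
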