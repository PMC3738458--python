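"""Transcript-centric annotation store with exon/transcript/gene queries.

The :class:`TranscriptStore` distills a GTF or GFF3 gene model into a small
relational core — an exon table, a transcript table, and a splicing table
linking them with per-transcript exon ranks — mirroring how transcript
databases are organized in genome-annotation practice. Ranks run 1..k within
each transcript, ascending with genomic position on '+' transcripts and
descending on '-', so rank 1 is always the 5'-most exon.

Stores serialize to a single relocatable SQLite file with an embedded schema
version, accessible from any environment with SQLite bindings.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnnotationTable, IntegerRanges, RangesError
from .genomic import GenomicRanges, GenomicRangesList, SeqInfo, group_genomic
from .io import read_gff

__all__ = [
    "TranscriptStore",
    "store_from_gff",
    "exons",
    "exons_by",
    "transcripts",
    "genes",
    "store_save",
    "store_load",
]

SCHEMA_VERSION = 1

_EXON_COLS = ["exon_id", "seq_name", "start", "end", "strand", "exon_name"]
_TX_COLS = ["tx_id", "tx_name", "gene_id"]
_SPLICING_COLS = ["tx_id", "exon_id", "exon_rank"]
_CDS_COLS = ["tx_id", "exon_id", "cds_start", "cds_end"]


class TranscriptStore:
    """Relational gene-model store: exon + transcript + splicing tables."""

    def __init__(self, exon_table: pd.DataFrame, transcript_table: pd.DataFrame,
                 splicing_table: pd.DataFrame, cds_table: pd.DataFrame | None = None,
                 seq_info: SeqInfo | None = None,
                 metadata: dict | None = None):
        self.exon_table = exon_table.reset_index(drop=True)[_EXON_COLS]
        self.transcript_table = transcript_table.reset_index(drop=True)[_TX_COLS]
        self.splicing_table = splicing_table.reset_index(drop=True)[_SPLICING_COLS]
        if cds_table is None:
            cds_table = pd.DataFrame(columns=_CDS_COLS)
        self.cds_table = cds_table.reset_index(drop=True)[_CDS_COLS]
        self.seq_info = seq_info or SeqInfo(
            sorted(self.exon_table["seq_name"].astype(str).unique()))
        self.metadata = dict(metadata or {})
        self._validate()

    @classmethod
    def empty(cls) -> "TranscriptStore":
        return cls(pd.DataFrame(columns=_EXON_COLS),
                   pd.DataFrame(columns=_TX_COLS),
                   pd.DataFrame(columns=_SPLICING_COLS))

    def _validate(self):
        exo = self.exon_table.set_index("exon_id")
        for tx_id, grp in self.splicing_table.groupby("tx_id"):
            ranks = sorted(grp["exon_rank"].tolist())
            if ranks != list(range(1, len(ranks) + 1)):
                raise RangesError(
                    f"transcript {tx_id!r}: exon ranks {ranks} are not 1..k")
            ex = exo.loc[grp["exon_id"]]
            if ex["seq_name"].nunique() > 1 or ex["strand"].nunique() > 1:
                raise RangesError(
                    f"transcript {tx_id!r}: exons span multiple sequences "
                    "or strands")

    @property
    def n_exons(self) -> int:
        return len(self.exon_table)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_table)

    @property
    def n_genes(self) -> int:
        return self.transcript_table["gene_id"].nunique()

    def __repr__(self) -> str:
        return (f"TranscriptStore({self.n_genes} genes, "
                f"{self.n_transcripts} transcripts, {self.n_exons} exons)")

    def equals(self, other: "TranscriptStore") -> bool:
        def norm(df, keys):
            return df.astype(str).sort_values(keys).reset_index(drop=True)
        return (norm(self.exon_table, ["exon_id"]).equals(
                    norm(other.exon_table, ["exon_id"]))
                and norm(self.transcript_table, ["tx_id"]).equals(
                    norm(other.transcript_table, ["tx_id"]))
                and norm(self.splicing_table, ["tx_id", "exon_rank"]).equals(
                    norm(other.splicing_table, ["tx_id", "exon_rank"])))


def _resolve_gff3_parents(feats: pd.DataFrame):
    """Map exon rows to (tx_id, gene_id) via one level of Parent indirection."""
    ann = feats
    ids = {}
    for _, row in ann.iterrows():
        if row.get("ID"):
            ids[row["ID"]] = row
    tx_ids, gene_ids = [], []
    for _, row in ann.iterrows():
        if str(row["feature"]).lower() != "exon":
            tx_ids.append(None)
            gene_ids.append(None)
            continue
        parent = row.get("Parent")
        if not parent:
            raise RangesError("GFF3 exon without a Parent attribute")
        tx_ids.append(parent)
        parent_row = ids.get(parent)
        gene_ids.append(parent_row.get("Parent") if parent_row is not None
                        else None)
    return tx_ids, gene_ids


def store_from_gff(path, dialect: str = "gtf",
                   seq_info: SeqInfo | None = None,
                   metadata: dict | None = None) -> TranscriptStore:
    """Build a store from a GTF or GFF3 file.

    GTF ``gene_id``/``transcript_id`` attributes are authoritative; GFF3
    resolves exon -> mRNA -> gene through Parent/ID with one level of
    indirection. Exon ranks are taken from the ``exon_rank``/``exon_number``
    attribute when present, otherwise assigned from strand-aware position
    order ((start, end) lexicographic, reversed on '-'). Exons identical in
    coordinates and strand are shared between transcripts. The result is
    independent of input line order.
    """
    g = read_gff(path, dialect=dialect, seq_info=seq_info)
    ann = g.annotations.to_frame()
    ann["seq_name"] = g.seq_names
    ann["start"] = g.starts
    ann["end"] = g.ends
    ann["strand"] = g.strand
    is_exon = ann["feature"].astype(str).str.lower() == "exon"
    ex = ann[is_exon].copy()
    if ex.empty:
        return TranscriptStore.empty()

    if dialect == "gtf":
        for col in ("gene_id", "transcript_id"):
            if col not in ex.columns or ex[col].isna().any():
                raise RangesError(f"GTF exon rows must carry {col!r}")
        ex["tx_key"] = ex["transcript_id"]
        ex["gene_key"] = ex["gene_id"]
    else:
        tx_ids, gene_ids = _resolve_gff3_parents(ann)
        ann2 = ann.assign(tx_key=tx_ids, gene_key=gene_ids)
        ex = ann2[is_exon].copy()
        if ex["tx_key"].isna().any():
            raise RangesError("GFF3 exon rows must carry a Parent transcript")

    # canonical exon identity: (seq, start, end, strand)
    key_cols = ["seq_name", "start", "end", "strand"]
    uniq = (ex[key_cols + [c for c in ("exon_id", "exon_name") if c in ex]]
            .drop_duplicates(subset=key_cols)
            .sort_values(["seq_name", "start", "end", "strand"])
            .reset_index(drop=True))
    if "exon_id" in uniq.columns and uniq["exon_id"].notna().all():
        uniq["exon_id"] = uniq["exon_id"].astype(str)
    else:
        uniq["exon_id"] = [str(i + 1) for i in range(len(uniq))]
    if "exon_name" not in uniq.columns:
        uniq["exon_name"] = None
    exon_table = uniq[_EXON_COLS[1:-1] + ["exon_id", "exon_name"]][_EXON_COLS]
    lookup = {tuple(row[k] for k in key_cols): row["exon_id"]
              for _, row in exon_table.iterrows()}
    ex["exon_id"] = [lookup[tuple(r[k] for k in key_cols)]
                     for _, r in ex.iterrows()]

    # transcript table
    tx_rows = (ex.groupby("tx_key", sort=True)
               .agg(gene_id=("gene_key", "first"),
                    seqs=("seq_name", "nunique"),
                    strands=("strand", "nunique"))
               .reset_index())
    bad = tx_rows[(tx_rows["seqs"] > 1) | (tx_rows["strands"] > 1)]
    if not bad.empty:
        raise RangesError(
            f"transcript {bad['tx_key'].iloc[0]!r} has exons on multiple "
            "sequences or strands")
    tx_name_col = "transcript_name" if "transcript_name" in ex.columns else None
    names = (ex.groupby("tx_key")[tx_name_col].first()
             if tx_name_col else None)
    transcript_table = pd.DataFrame({
        "tx_id": tx_rows["tx_key"].astype(str),
        "tx_name": (names.loc[tx_rows["tx_key"]].tolist()
                    if names is not None else [None] * len(tx_rows)),
        "gene_id": tx_rows["gene_id"].astype(str),
    })

    # splicing table with ranks
    rank_attr = next((c for c in ("exon_rank", "exon_number") if c in ex.columns),
                     None)
    spl_rows = []
    for tx_id, grp in ex.groupby("tx_key", sort=True):
        grp = grp.drop_duplicates(subset=key_cols)
        if rank_attr and grp[rank_attr].notna().all():
            grp = grp.assign(_rank=grp[rank_attr].astype(int))
        else:
            asc = grp["strand"].iloc[0] != "-"
            grp = grp.sort_values(["start", "end"], ascending=asc)
            grp = grp.assign(_rank=np.arange(1, len(grp) + 1))
        for _, row in grp.iterrows():
            spl_rows.append({"tx_id": str(tx_id), "exon_id": row["exon_id"],
                             "exon_rank": int(row["_rank"])})
    splicing_table = pd.DataFrame(spl_rows, columns=_SPLICING_COLS)

    meta = {"source": str(path) if not hasattr(path, "read") else "<stream>",
            "dialect": dialect}
    meta.update(metadata or {})
    return TranscriptStore(exon_table, transcript_table, splicing_table,
                           seq_info=seq_info, metadata=meta)


def _exon_granges(store: TranscriptStore, df: pd.DataFrame,
                  columns: list[str] | None = None) -> GenomicRanges:
    ann_cols = {}
    for c in (columns or []):
        if c in df.columns:
            ann_cols[c] = df[c].tolist()
        else:
            raise RangesError(f"unknown annotation column {c!r}")
    ranges = IntegerRanges(df["start"].to_numpy(dtype=np.int64),
                           df["end"].to_numpy(dtype=np.int64),
                           annotations=AnnotationTable(ann_cols,
                                                       n_rows=len(df)))
    return GenomicRanges(df["seq_name"].tolist(), ranges,
                         df["strand"].tolist(), store.seq_info)


def exons(store: TranscriptStore, filters: dict | None = None,
          columns: list[str] | None = None) -> GenomicRanges:
    """One range per exon matching all filters, with requested columns.

    Filter keys and column names may reference exon attributes plus
    ``tx_id`` and ``gene_id``; since an exon can belong to several
    transcripts, ``tx_id`` is delivered as a list-valued column.
    """
    df = store.exon_table.copy()
    spl = store.splicing_table.merge(store.transcript_table, on="tx_id")
    tx_of = spl.groupby("exon_id")["tx_id"].apply(list)
    gene_of = spl.groupby("exon_id")["gene_id"].apply(lambda s: sorted(set(s)))
    df["tx_id"] = df["exon_id"].map(tx_of).apply(
        lambda v: v if isinstance(v, list) else [])
    df["gene_id"] = df["exon_id"].map(gene_of).apply(
        lambda v: v if isinstance(v, list) else [])
    for key, want in (filters or {}).items():
        if key not in df.columns:
            raise RangesError(f"unknown filter attribute {key!r}")
        wanted = {str(w) for w in (want if isinstance(want, (list, tuple, set))
                                   else [want])}
        if key in ("tx_id", "gene_id"):
            mask = df[key].apply(lambda v: bool(wanted & {str(x) for x in v}))
        else:
            mask = df[key].astype(str).isin(wanted)
        df = df[mask]
    df = df.sort_values(["seq_name", "start", "end"]).reset_index(drop=True)
    return _exon_granges(store, df, columns)


def exons_by(store: TranscriptStore, group: str = "transcript"
             ) -> GenomicRangesList:
    """Exons grouped by transcript (rank order) or gene (position order),
    with exon_id/exon_name/exon_rank annotations on each range."""
    if group not in ("transcript", "gene"):
        raise RangesError(f"unknown grouping {group!r}; use transcript or gene")
    spl = (store.splicing_table
           .merge(store.exon_table, on="exon_id")
           .merge(store.transcript_table, on="tx_id"))
    if group == "transcript":
        spl = spl.sort_values(["tx_id", "exon_rank"])
        factor = spl["tx_id"]
    else:
        spl = (spl.drop_duplicates(subset=["gene_id", "seq_name", "start",
                                           "end", "strand"])
               .sort_values(["gene_id", "start", "end"]))
        factor = spl["gene_id"]
    spl = spl.reset_index(drop=True)
    flat = _exon_granges(store, spl, columns=None).with_annotations(
        AnnotationTable({"exon_id": spl["exon_id"].tolist(),
                         "exon_name": spl["exon_name"].tolist(),
                         "exon_rank": spl["exon_rank"].tolist()}))
    return group_genomic(flat, factor.tolist())


def transcripts(store: TranscriptStore) -> GenomicRanges:
    """Transcript bounds: the span of each transcript's exons, with
    tx_id/tx_name/gene_id annotations."""
    spl = (store.splicing_table
           .merge(store.exon_table, on="exon_id")
           .groupby("tx_id")
           .agg(seq_name=("seq_name", "first"), strand=("strand", "first"),
                start=("start", "min"), end=("end", "max"))
           .reset_index()
           .merge(store.transcript_table, on="tx_id")
           .sort_values("tx_id")
           .reset_index(drop=True))
    return _exon_granges(store, spl, columns=["tx_id", "tx_name", "gene_id"])


def genes(store: TranscriptStore) -> GenomicRanges:
    """Gene spans: the span of each gene's transcript bounds."""
    tx = transcripts(store)
    df = pd.DataFrame({
        "gene_id": [str(v) for v in tx.annotations.column("gene_id")],
        "seq_name": tx.seq_names, "strand": tx.strand,
        "start": tx.starts, "end": tx.ends,
    })
    agg = (df.groupby("gene_id")
           .agg(seq_name=("seq_name", "first"), strand=("strand", "first"),
                start=("start", "min"), end=("end", "max"))
           .reset_index()
           .sort_values("gene_id")
           .reset_index(drop=True))
    return _exon_granges(store, agg, columns=["gene_id"])


# -- persistence ---------------------------------------------------------------


def store_save(store: TranscriptStore, path):
    """Serialize to a single-file SQLite database."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
        rows = [("schema_version", str(SCHEMA_VERSION)),
                ("genome", store.seq_info.genome or "")]
        rows += [(f"meta:{k}", str(v)) for k, v in store.metadata.items()]
        con.executemany("INSERT INTO meta VALUES (?, ?)", rows)
        con.execute("CREATE TABLE seqinfo (seq_name TEXT PRIMARY KEY, "
                    "length INTEGER)")
        con.executemany("INSERT INTO seqinfo VALUES (?, ?)",
                        [(n, store.seq_info.seq_lengths[n])
                         for n in store.seq_info.seq_names])
        store.exon_table.to_sql("exon", con, index=False)
        store.transcript_table.to_sql("transcript", con, index=False)
        store.splicing_table.to_sql("splicing", con, index=False)
        store.cds_table.to_sql("cds", con, index=False)
        con.commit()
    finally:
        con.close()


def store_load(path) -> TranscriptStore:
    """Load a store saved by :func:`store_save`; errors on schema mismatch."""
    con = sqlite3.connect(f"file:{Path(path)}?mode=ro", uri=True)
    try:
        meta = dict(con.execute("SELECT key, value FROM meta").fetchall())
        version = int(meta.get("schema_version", "-1"))
        if version != SCHEMA_VERSION:
            raise RangesError(
                f"store schema version {version} != supported {SCHEMA_VERSION}")
        si_rows = con.execute(
            "SELECT seq_name, length FROM seqinfo").fetchall()
        seq_info = SeqInfo([r[0] for r in si_rows],
                           {r[0]: int(r[1]) for r in si_rows if r[1]},
                           genome=meta.get("genome") or None)
        exon = pd.read_sql("SELECT * FROM exon", con)
        tx = pd.read_sql("SELECT * FROM transcript", con)
        spl = pd.read_sql("SELECT * FROM splicing", con)
        cds = pd.read_sql("SELECT * FROM cds", con)
        metadata = {k[5:]: v for k, v in meta.items() if k.startswith("meta:")}
        return TranscriptStore(exon, tx, spl, cds, seq_info=seq_info,
                               metadata=metadata)
    finally:
        con.close()
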