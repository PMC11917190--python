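"""Readers and writers for the plain-text formats the pipeline exchanges.

bedGraph and BED go through pandas; FASTA through Biopython.  Parsing
errors are reported with the 1-based line number of the first offending
record so malformed count files fail loudly rather than silently losing
signal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def _validated(df: pd.DataFrame, numeric_cols, path) -> pd.DataFrame:
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: malformed record at line {line} (column {col!r})")
        df[col] = coerced
    return df


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph (chrom, start, end, value)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"], dtype=str,
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty bedGraph") from None
    if df.empty:
        raise ValueError(f"{path}: empty bedGraph")
    df = _validated(df, ["start", "end", "value"], path)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path, n_cols: int | None = None) -> pd.DataFrame:
    """Read BED3..BED6 (extra columns beyond 6 are kept, unnamed)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty BED") from None
    if df.empty:
        raise ValueError(f"{path}: empty BED")
    ncol = df.shape[1] if n_cols is None else n_cols
    df.columns = (BED6_COLS + [f"extra{i}" for i in range(max(0, df.shape[1] - 6))])[: df.shape[1]]
    df = _validated(df, ["start", "end"], path)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df.iloc[:, :ncol] if n_cols else df


def write_bed(df: pd.DataFrame, path, cols=None) -> None:
    cols = cols or [c for c in BED6_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
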