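"""Readers and writers for the pipeline's tab-separated artifacts.

All tables are TSV with a header row; lines starting with '#' are comments;
CRLF input is accepted.  Genomic coordinates are 0-based half-open
everywhere internally; BED-like depth input may be converted from 1-based
inclusive with ``one_based=True``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_window_depths", "write_window_depths",
    "read_markers", "write_markers",
    "read_counts", "write_counts",
    "read_alignments", "write_alignments",
    "write_grouping", "read_grouping_table",
    "write_fasta", "read_fasta",
    "write_tsv", "read_tsv",
]

_SCHEMAS = {
    "window_depths": ["contig_id", "start", "end", "depth"],
    "markers": ["marker_id", "contig_id", "start", "end", "copy_class", "W"],
    "alignments": ["read_id", "contig_id", "contig_start", "contig_end",
                   "aligned_bp"],
}


class ParseError(ValueError):
    pass


def read_tsv(path, columns: list[str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pandas reports the offending line number
        raise ParseError(f"{path}: {exc}") from exc
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_window_depths(path, one_based: bool = False) -> pd.DataFrame:
    df = read_tsv(path, _SCHEMAS["window_depths"])
    if one_based:
        df = df.assign(start=df["start"] - 1)
    bad = df.index[(df["end"] <= df["start"]) | (df["depth"] < 0)]
    if len(bad):
        raise ParseError(f"{path}: invalid window at data row {bad[0] + 1}")
    return df


def write_window_depths(df: pd.DataFrame, path) -> None:
    write_tsv(df[_SCHEMAS["window_depths"]], path)


def read_markers(path) -> pd.DataFrame:
    return read_tsv(path, _SCHEMAS["markers"])


def write_markers(df: pd.DataFrame, path) -> None:
    write_tsv(df[_SCHEMAS["markers"]], path)


def read_counts(path) -> pd.DataFrame:
    df = read_tsv(path)
    if df.columns[0] != "marker_id":
        raise ParseError(f"{path}: first column must be marker_id")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    write_tsv(df, path)


def read_alignments(path) -> pd.DataFrame:
    df = read_tsv(path, _SCHEMAS["alignments"])
    bad = df.index[df["aligned_bp"] > (df["contig_end"] - df["contig_start"])]
    if len(bad):
        raise ParseError(
            f"{path}: aligned_bp exceeds alignment span at data row {bad[0] + 1}")
    return df


def write_alignments(df: pd.DataFrame, path) -> None:
    write_tsv(df[_SCHEMAS["alignments"]], path)


def write_grouping(df: pd.DataFrame, path) -> None:
    write_tsv(df, path)


def read_grouping_table(path) -> pd.DataFrame:
    return read_tsv(path, ["marker_id", "contig_id", "group_id"])


def write_fasta(records, path) -> None:
    """Write (name, sequence) pairs as FASTA, 80 columns."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
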