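"""Readers and writers for the pipeline's plain-text artifacts.

Dialect is fixed for reproducibility: tab-separated, UTF-8, '.' decimal,
"NA" for missing. A GEO-series-matrix-like dialect ('!'-prefixed comment
lines, first column = gene id) is accepted on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .preprocess import VALID_RECURRENCE, StudyExpression

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_series_matrix_like",
]

_CSV_KW = dict(sep="\t", na_rep="NA")


def write_expression_tsv(expression: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x sample matrix: header row of sample ids, gene id column."""
    expression.to_csv(path, index_label="gene_id", **_CSV_KW)


def _dedupe_genes(frame: pd.DataFrame, path) -> pd.DataFrame:
    if frame.index.has_duplicates:
        n = int(frame.index.duplicated().sum())
        warnings.warn(f"{path}: {n} duplicate gene id(s); keeping first occurrence")
        frame = frame[~frame.index.duplicated(keep="first")]
    return frame


def _check_header_duplicates(path: str | Path) -> None:
    # pandas silently renames duplicate header fields, so inspect the raw line
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")[1:]
            seen = set()
            for f in fields:
                if f in seen:
                    raise ValueError(f"{path}: duplicate sample id {f!r}")
                seen.add(f)
            return


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV; duplicate gene ids keep the first row."""
    _check_header_duplicates(path)
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip"
    )
    frame.index.name = "gene_id"
    return _dedupe_genes(frame, path)


def read_series_matrix_like(path: str | Path) -> pd.DataFrame:
    """Read a series-matrix-like TSV, skipping '!'-prefixed comment lines."""
    _check_header_duplicates(path)
    frame = pd.read_csv(
        path, sep="\t", index_col=0, comment="!", na_values=["NA"],
        float_precision="round_trip",
    )
    frame.index.name = "gene_id"
    return _dedupe_genes(frame, path)


def read_study_tsv(path: str | Path, study_id: str, scale: str = "log2") -> StudyExpression:
    return StudyExpression(study_id=study_id, expression=read_expression_tsv(path), scale=scale)


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index_label="sample_id", **_CSV_KW)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (study_id, who_grade, recurrence)."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={"recurrence": str})
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    required = {"study_id", "who_grade", "recurrence"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {sorted(missing)}")
    meta["who_grade"] = meta["who_grade"].astype(int)
    bad = set(meta["recurrence"]) - VALID_RECURRENCE
    if bad:
        raise ValueError(f"{path}: invalid recurrence value(s) {sorted(bad)}")
    meta.index.name = "sample_id"
    return meta
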