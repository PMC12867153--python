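"""Delimited-text readers and writers for the pipeline's tables.

Cell tables, sample metadata and comparison tables are plain CSV; count
matrices are CSV with genes as rows, segments as columns and a boolean
``is_negative_probe`` annotation column. Floats are written with full
``repr`` precision so a round trip is lossless to the last ulp.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .geomx import CountMatrix
from .table import validate_cell_table

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_meta",
    "write_sample_meta",
    "write_json",
]


def write_cell_table(table: pd.DataFrame, path) -> None:
    validate_cell_table(table)
    table.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_cell_table(table)
    return table


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_sample_meta(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    out = matrix.counts.rename_axis("gene_id")
    out.insert(0, "is_negative_probe", out.index.isin(matrix.negative_probes))
    out.to_csv(path)


def read_count_matrix(path) -> CountMatrix:
    df = pd.read_csv(path, index_col="gene_id").rename_axis(None)
    neg = df.index[df["is_negative_probe"].astype(bool)].tolist()
    counts = df.drop(columns=["is_negative_probe"])
    return CountMatrix(counts=counts, negative_probes=neg)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
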