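"""Per-cell table conventions.

A cell table is a :class:`pandas.DataFrame` with one row per segmented cell.
Reserved columns are ``sample_id``, ``cell_id``, ``x``, ``y``, the optional
``area`` and ``cell_class``; every remaining column is treated as a marker
intensity channel. ``cell_class`` carries ground truth in synthetic tables and
inferred phenotypes otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("sample_id", "cell_id", "x", "y", "area", "cell_class")


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Names of the marker-intensity columns of *table*, in column order."""
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


def validate_cell_table(table: pd.DataFrame) -> None:
    """Check the cell-table invariants, raising ``ValueError`` on violation.

    Coordinates must be finite, intensities non-negative, and
    ``(sample_id, cell_id)`` unique. Coincident coordinates are permitted:
    segmentation centroids can collide after rounding.
    """
    for col in ("sample_id", "cell_id", "x", "y"):
        if col not in table.columns:
            raise ValueError(f"cell table lacks required column {col!r}")
    xy = table[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("cell coordinates must be finite")
    if table.duplicated(subset=["sample_id", "cell_id"]).any():
        raise ValueError("(sample_id, cell_id) pairs must be unique")
    markers = marker_columns(table)
    if markers:
        vals = table[markers].to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise ValueError("marker intensities must be non-negative")
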