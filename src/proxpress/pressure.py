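"""Proximal-pressure neighborhood statistic for multiplexed imaging.

For each cancer cell, the proximal pressure of a marker is the 90th
percentile (linear-interpolation convention) of that marker's expression over
all cells — of any class, the index cell excluded — whose centroid lies
within the proximity constraint: a radius expressed in multiples of the
estimated cell diameter (default 2 diameters, i.e. the cell's own diameter
plus one more). Per-sample pressures are summarized by the median over
cancer cells with non-empty neighborhoods, and sample summaries are placed
on a common scale as cohort z-scores per marker.

Cells with empty neighborhoods contribute missing values, never zeros: a
zero would fabricate low pressure where nothing was measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import stats as pstats
from .table import marker_columns

__all__ = [
    "UnusableSampleError",
    "PressureProfile",
    "CohortPressure",
    "estimate_cell_diameter",
    "neighborhood",
    "proximal_pressure",
    "cohort_pressure",
    "compare_pressure",
]

PRESSURE_PERCENTILE = 90.0


class UnusableSampleError(ValueError):
    """The sample cannot support the requested spatial estimate."""


@dataclass
class PressureProfile:
    """Per-cancer-cell pressures of one marker in one sample."""

    sample_id: str
    marker: str
    cell_diameter: float
    radius: float
    values: pd.Series  # indexed by cancer cell_id; NaN where neighborhood empty
    n_empty: int
    empty: bool = False  # True when the sample has no cancer cells

    @property
    def median(self) -> float:
        """Sample summary: median over non-missing per-cell pressures."""
        v = self.values.dropna()
        return float(v.median()) if len(v) else np.nan


@dataclass
class CohortPressure:
    """Sample x marker pressure summaries with cohort z-scores."""

    medians: pd.DataFrame  # rows: sample_id, columns: marker
    zscores: pd.DataFrame  # same shape; mean 0, population-variance 1 per marker
    profiles: dict[tuple[str, str], PressureProfile] = field(default_factory=dict)


def estimate_cell_diameter(table: pd.DataFrame, cancer_mask: pd.Series) -> float:
    """Estimate the cell diameter from the cancer cells of one sample.

    With areas, the diameter is the median area-equivalent diameter
    2 * sqrt(area / pi) over cancer cells; without areas it is the median
    nearest-neighbor distance among cancer cells (which needs >= 2 of them).
    """
    cancer = table.loc[np.asarray(cancer_mask, dtype=bool)]
    if len(cancer) == 0:
        raise UnusableSampleError("no cancer cells: diameter not estimable")
    if "area" in cancer.columns and cancer["area"].notna().all():
        d = float(np.median(2.0 * np.sqrt(cancer["area"].to_numpy(dtype=float) / np.pi)))
    else:
        if len(cancer) < 2:
            raise UnusableSampleError(
                "single cancer cell without area: diameter not estimable"
            )
        xy = cancer[["x", "y"]].to_numpy(dtype=float)
        dist, _ = cKDTree(xy).query(xy, k=2)
        d = float(np.median(dist[:, 1]))
    if not d > 0:
        raise UnusableSampleError("estimated cell diameter is not positive")
    return d


def neighborhood(table: pd.DataFrame, index_cell: str, radius: float) -> list[str]:
    """Cell ids within Euclidean distance <= radius of *index_cell*.

    All cells of any class count; the index cell itself is excluded; a cell
    at distance exactly equal to the radius is included. The table must
    contain a single sample (cell ids are only unique within a sample).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if table["sample_id"].nunique() > 1:
        raise ValueError("neighborhood operates on a single sample")
    hit = table.index[table["cell_id"] == index_cell]
    if len(hit) == 0:
        raise KeyError(f"index cell {index_cell!r} not in table")
    i = hit[0]
    xy = table[["x", "y"]].to_numpy(dtype=float)
    pos = table.index.get_indexer([i])[0]
    d = np.hypot(xy[:, 0] - xy[pos, 0], xy[:, 1] - xy[pos, 1])
    keep = (d <= radius) & (np.arange(len(table)) != pos)
    return table["cell_id"].to_numpy()[keep].tolist()


def proximal_pressure(
    table: pd.DataFrame,
    markers: str | list[str] | None = None,
    radius_in_diameters: float = 2.0,
    cancer_mask: pd.Series | None = None,
) -> dict[str, PressureProfile]:
    """Proximal pressure of each marker for every cancer cell of one sample.

    ``cancer_mask`` is a boolean series aligned with the table (e.g.
    ``GatingResult.labels`` or ``table.cell_class == "cancer"``). Marker
    values are used as given — normalize upstream if z-scale pressures are
    wanted. Returns one :class:`PressureProfile` per marker; with zero
    cancer cells the profiles are empty and flagged, not an error.
    """
    if table["sample_id"].nunique() > 1:
        raise ValueError("proximal_pressure operates on a single sample")
    sample_id = str(table["sample_id"].iloc[0]) if len(table) else ""
    if isinstance(markers, str):
        markers = [markers]
    if markers is None:
        markers = marker_columns(table)
    missing = [m for m in markers if m not in table.columns]
    if missing:
        raise ValueError(f"markers absent from table: {missing}")
    if cancer_mask is None:
        if "cell_class" not in table.columns:
            raise ValueError("no cancer_mask given and no cell_class column")
        cancer_mask = table["cell_class"] == "cancer"
    mask = np.asarray(cancer_mask, dtype=bool)

    if mask.sum() == 0:
        empty = pd.Series(dtype=float, name="pressure")
        return {
            m: PressureProfile(sample_id, m, np.nan, np.nan, empty, 0, empty=True)
            for m in markers
        }

    diameter = estimate_cell_diameter(table, pd.Series(mask, index=table.index))
    radius = radius_in_diameters * diameter
    xy = table[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    cancer_pos = np.flatnonzero(mask)
    hoods = tree.query_ball_point(xy[cancer_pos], r=radius)
    cancer_ids = table["cell_id"].to_numpy()[cancer_pos]

    vals = table[markers].to_numpy(dtype=float)
    out = np.full((len(cancer_pos), len(markers)), np.nan)
    n_empty = 0
    frac_rank = PRESSURE_PERCENTILE / 100.0
    for row, (pos, hood) in enumerate(zip(cancer_pos, hoods)):
        neigh = [j for j in hood if j != pos]
        if not neigh:
            n_empty += 1
            continue
        # 90th percentile, linear interpolation between order statistics
        # (matches numpy's default "linear" convention exactly)
        sub = np.sort(vals[neigh], axis=0)
        k = sub.shape[0]
        q = frac_rank * (k - 1)
        lo = int(q)
        hi = min(lo + 1, k - 1)
        w = q - lo
        out[row] = sub[lo] * (1.0 - w) + sub[hi] * w
    return {
        m: PressureProfile(
            sample_id=sample_id,
            marker=m,
            cell_diameter=diameter,
            radius=radius,
            values=pd.Series(out[:, j], index=cancer_ids, name="pressure"),
            n_empty=n_empty,
        )
        for j, m in enumerate(markers)
    }


def cohort_pressure(
    tables: dict[str, pd.DataFrame],
    markers: list[str] | None = None,
    radius_in_diameters: float = 2.0,
    cancer_masks: dict[str, pd.Series] | None = None,
    keep_profiles: bool = False,
) -> CohortPressure:
    """Per-sample pressure medians and cohort z-scores across samples.

    z-scores standardize each marker's sample medians with the population
    (n) denominator, so across samples they have mean 0 and variance 1
    whenever at least two samples have non-missing summaries.
    """
    rows = {}
    profiles: dict[tuple[str, str], PressureProfile] = {}
    for sample_id, table in tables.items():
        mask = cancer_masks[sample_id] if cancer_masks is not None else None
        profs = proximal_pressure(table, markers, radius_in_diameters, mask)
        rows[sample_id] = {m: p.median for m, p in profs.items()}
        if keep_profiles:
            for m, p in profs.items():
                profiles[(sample_id, m)] = p
    medians = pd.DataFrame.from_dict(rows, orient="index")
    medians.index.name = "sample_id"
    z = medians.copy()
    for m in medians.columns:
        v = medians[m]
        ok = v.notna()
        if ok.sum() >= 2:
            sd = v[ok].std(ddof=0)
            z[m] = (v - v[ok].mean()) / sd if sd > 0 else 0.0
        else:
            z[m] = np.nan
    return CohortPressure(medians=medians, zscores=z, profiles=profiles)


def compare_pressure(
    summaries: pd.DataFrame,
    groups: pd.Series,
    markers: list[str] | None = None,
    group_a: str = "sensitive",
    group_b: str = "resistant",
) -> pd.DataFrame:
    """Group comparison of per-sample pressure summaries, marker by marker.

    Two-sided Wilcoxon rank-sum on the sample summaries of ``group_b``
    versus ``group_a`` per marker, Benjamini-Hochberg FDR across the
    testable markers. Direction is the sign of (group_b median - group_a
    median). A marker with fewer than two usable summaries in either group
    is reported as untestable rather than silently dropped.
    """
    if markers is None:
        markers = list(summaries.columns)
    groups = groups.reindex(summaries.index)
    recs = []
    for m in markers:
        v = summaries[m]
        a = v[(groups == group_a) & v.notna()].to_numpy(dtype=float)
        b = v[(groups == group_b) & v.notna()].to_numpy(dtype=float)
        rec = {
            "marker": m,
            "n_" + group_a: len(a),
            "n_" + group_b: len(b),
            "statistic": np.nan,
            "p_value": np.nan,
            "fdr": np.nan,
            "direction": 0,
            "note": "",
        }
        if len(a) < 2 or len(b) < 2:
            rec["note"] = "untestable: fewer than 2 summaries in a group"
        else:
            res = pstats.rank_sum_test(b, a)
            rec["statistic"] = res.statistic
            rec["p_value"] = res.p_value
            rec["direction"] = int(np.sign(np.median(b) - np.median(a)))
            if res.degenerate:
                rec["note"] = "degenerate: all values identical"
        recs.append(rec)
    out = pd.DataFrame(recs)
    testable = out["p_value"].notna()
    if testable.any():
        out.loc[testable, "fdr"] = pstats.bh_fdr(out.loc[testable, "p_value"].tolist())
    return out
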