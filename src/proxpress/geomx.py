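"""Segment-level normalization for compartment-resolved spatial profiling.

Implements the standard digital-spatial-profiler processing chain for a
segment x gene count matrix: a per-segment limit of quantification (LOQ)
derived from negative probes, LOQ-based gene filtering, and third-quartile
(Q3) normalization that aligns every segment's 75th-percentile count to a
common geometric-mean target.

The LOQ rule "geometric mean plus 2 SDs of the negative probes" admits two
readings; both are implemented. The default "geometric" mode is the
platform-standard geoMean x geoSD^2 (two geometric standard deviations above
the geometric mean); the "arithmetic" mode is the literal mean + 2 * SD.
Standard deviations use the population (n) denominator in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "FilterMasks",
    "NormalizedMatrix",
    "compute_loq",
    "filter_by_loq",
    "q3_normalize",
]

ZERO_PSEUDOCOUNT = 0.5  # added to zero counts before log operations


@dataclass
class CountMatrix:
    """Genes x segments count matrix with annotated negative probes.

    ``counts`` rows are gene (and negative-probe) ids, columns segment ids.
    ``negative_probes`` must be a nonempty strict subset of the row index.
    ``segment_labels`` optionally maps segments to compartment labels such
    as "PanCK+" or "CD45+".
    """

    counts: pd.DataFrame
    negative_probes: list[str]
    segment_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        probes = list(self.negative_probes)
        if not probes:
            raise ValueError("negative_probes must be nonempty")
        missing = set(probes) - set(self.counts.index)
        if missing:
            raise ValueError(f"negative probes absent from matrix: {sorted(missing)}")
        if len(probes) >= len(self.counts.index):
            raise ValueError("negative probes must be a strict subset of genes")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.negative_probes = probes

    @property
    def gene_ids(self) -> list[str]:
        """Row ids that are genes, i.e. not negative probes."""
        neg = set(self.negative_probes)
        return [g for g in self.counts.index if g not in neg]

    @property
    def segment_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class FilterMasks:
    """Boolean retention masks produced by LOQ filtering."""

    genes: pd.Series  # indexed by gene id (negative probes always False)
    segments: pd.Series  # indexed by segment id


@dataclass
class NormalizedMatrix:
    """Q3-normalized counts plus the per-segment factors used."""

    counts: pd.DataFrame
    q3_factors: pd.Series
    q3_target: float
    gene_mask: pd.Series
    segment_mask: pd.Series
    loq: pd.Series | None = None
    flags: list[str] = field(default_factory=list)


def _logs_with_pseudocount(values: np.ndarray) -> np.ndarray:
    v = values.astype(float).copy()
    v[v == 0] = ZERO_PSEUDOCOUNT
    return np.log(v)


def compute_loq(matrix: CountMatrix, mode: str = "geometric") -> pd.Series:
    """Per-segment limit of quantification from the negative probes.

    A segment whose negative probes are all zero is unquantifiable: its LOQ
    is NaN (callers treat NaN-LOQ segments as dropped). Zero counts receive
    a 0.5 pseudocount before log operations.
    """
    if mode not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown LOQ mode {mode!r}")
    neg = matrix.counts.loc[matrix.negative_probes]
    out = {}
    for seg in matrix.segment_ids:
        probes = neg[seg].to_numpy(dtype=float)
        if (probes == 0).all():
            out[seg] = np.nan
            continue
        if mode == "geometric":
            logs = _logs_with_pseudocount(probes)
            geo_mean = np.exp(logs.mean())
            geo_sd = np.exp(logs.std(ddof=0))
            out[seg] = geo_mean * geo_sd**2
        else:
            probes = probes.copy()
            probes[probes == 0] = ZERO_PSEUDOCOUNT
            out[seg] = probes.mean() + 2.0 * probes.std(ddof=0)
    return pd.Series(out, name=f"loq_{mode}")


def filter_by_loq(
    matrix: CountMatrix, loq: pd.Series, min_segment_fraction: float = 0.1
) -> FilterMasks:
    """Retain genes quantifiable in enough segments.

    A gene is retained iff its count strictly exceeds the segment LOQ in at
    least ``min_segment_fraction`` of the quantifiable segments (>= rule at
    the boundary). Negative probes are never retained.
    """
    if not 0.0 <= min_segment_fraction <= 1.0:
        raise ValueError("min_segment_fraction must lie in [0, 1]")
    seg_mask = loq.reindex(matrix.segment_ids).notna()
    usable = [s for s in matrix.segment_ids if seg_mask[s]]
    if not usable:
        raise ValueError("no quantifiable segments: all negative probes zero")
    above = matrix.counts[usable].gt(loq[usable], axis=1)
    frac = above.mean(axis=1)
    gene_mask = frac >= min_segment_fraction
    gene_mask[matrix.negative_probes] = False
    if not gene_mask.any():
        raise ValueError("LOQ filtering removed every gene")
    return FilterMasks(genes=gene_mask, segments=seg_mask)


def q3_normalize(
    matrix: CountMatrix, masks: FilterMasks | None = None
) -> NormalizedMatrix:
    """Q3 normalization: align segment 75th percentiles to a common target.

    Per retained segment, the factor is its 75th-percentile count over
    retained genes divided by the geometric mean of those percentiles across
    retained segments; all counts in the segment are divided by the factor.
    A segment with zero Q3 is flagged and excluded from the geometric-mean
    target (its factor is NaN and its counts pass through unchanged).
    """
    if masks is None:
        gene_mask = pd.Series(True, index=matrix.counts.index)
        gene_mask[matrix.negative_probes] = False
        seg_mask = pd.Series(True, index=matrix.segment_ids)
    else:
        gene_mask = masks.genes.reindex(matrix.counts.index, fill_value=False)
        seg_mask = masks.segments.reindex(matrix.segment_ids, fill_value=False)
    retained_genes = gene_mask[gene_mask].index
    retained_segs = [s for s in matrix.segment_ids if seg_mask[s]]
    if len(retained_genes) == 0 or not retained_segs:
        raise ValueError("Q3 normalization needs >= 1 retained gene and segment")

    q3 = matrix.counts.loc[retained_genes, retained_segs].quantile(0.75, axis=0)
    flags = []
    positive = q3 > 0
    for seg in q3.index[~positive]:
        flags.append(f"segment {seg}: zero Q3, excluded from normalization target")
        seg_mask[seg] = False
    if not positive.any():
        raise ValueError("every retained segment has zero Q3")
    target = float(np.exp(np.log(q3[positive]).mean()))
    factors = pd.Series(np.nan, index=matrix.segment_ids, name="q3_factor")
    factors[q3.index[positive]] = q3[positive] / target
    normalized = matrix.counts.div(factors.fillna(1.0), axis=1)
    return NormalizedMatrix(
        counts=normalized,
        q3_factors=factors,
        q3_target=target,
        gene_mask=gene_mask,
        segment_mask=seg_mask,
        flags=flags,
    )
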