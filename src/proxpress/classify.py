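"""Endocrine-response classification and gene-signature scoring.

A short presurgical course of an aromatase inhibitor suppresses estrogen
signalling; the on-treatment Ki67 labeling fraction of tumor cells then
separates endocrine-sensitive tumors (Ki67 <= 2.7%) from resistant ones
(Ki67 >= 7.4%), with the band in between called intermediate and excluded
from group analyses. Where Ki67 was measured by quantitative
immunofluorescence, the labeling index is ln(AQUA score + 0.01), the small
offset accommodating scores of zero.

Signature scoring summarizes a gene set per sample; the default cytolytic
set is {GZMA, PRF1}, scored as the geometric mean of expression with a
0.01 pseudocount.
"""

from __future__ import annotations

import math
from collections.abc import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CYTOLYTIC_GENES",
    "KI67_SENSITIVE_MAX",
    "KI67_RESISTANT_MIN",
    "ki67_index",
    "classify_response",
    "annotate_response",
    "signature_score",
]

CYTOLYTIC_GENES = ("GZMA", "PRF1")
KI67_SENSITIVE_MAX = 2.7  # boundary inclusive: <= 2.7% is sensitive
KI67_RESISTANT_MIN = 7.4  # boundary inclusive: >= 7.4% is resistant
AQUA_OFFSET = 0.01


def ki67_index(aqua_score: float) -> float:
    """Ki67 labeling index = ln(AQUA score + 0.01). Strictly increasing;
    inverts exactly via exp(index) - 0.01."""
    if aqua_score < 0:
        raise ValueError("AQUA score must be non-negative")
    return math.log(aqua_score + AQUA_OFFSET)


def classify_response(ki67_percent: float) -> str:
    """Map an on-treatment Ki67 percentage to a response label.

    <= 2.7 -> "sensitive"; >= 7.4 -> "resistant"; strictly between ->
    "intermediate" (excluded from two-group analyses).
    """
    if not 0.0 <= ki67_percent <= 100.0:
        raise ValueError("Ki67 percentage must lie in [0, 100]")
    if ki67_percent <= KI67_SENSITIVE_MAX:
        return "sensitive"
    if ki67_percent >= KI67_RESISTANT_MIN:
        return "resistant"
    return "intermediate"


def annotate_response(meta: pd.DataFrame, ki67_col: str = "ki67_percent") -> pd.DataFrame:
    """Add/overwrite a ``response`` column from on-treatment Ki67 values;
    samples without a Ki67 value get "unknown"."""
    out = meta.copy()
    out["response"] = [
        classify_response(v) if pd.notna(v) else "unknown" for v in out[ki67_col]
    ]
    return out


def signature_score(
    expr: Mapping[str, float] | pd.DataFrame,
    gene_set: tuple[str, ...] = CYTOLYTIC_GENES,
    method: str = "geomean",
    pseudocount: float = 0.01,
):
    """Score a gene set per sample.

    ``expr`` is either a mapping gene -> expression for one sample (returns
    a float; "geomean" only) or a samples x genes DataFrame (returns a
    Series per sample). "geomean" is the geometric mean of (expression +
    pseudocount) over the genes present; "meanz" is the mean of per-gene
    z-scores across the cohort (population denominator) and therefore has
    cohort mean zero. Genes missing from ``expr`` are dropped; an empty
    intersection is an error naming the missing genes.
    """
    if method not in ("geomean", "meanz"):
        raise ValueError(f"unknown scoring method {method!r}")
    single = isinstance(expr, Mapping)
    frame = pd.DataFrame([expr]) if single else expr
    present = [g for g in gene_set if g in frame.columns]
    if not present:
        raise KeyError(f"no signature genes present; missing: {list(gene_set)}")
    vals = frame[present].astype(float)
    if method == "geomean":
        if (vals.to_numpy() + pseudocount <= 0).any():
            raise ValueError("geomean needs expression + pseudocount > 0")
        scores = np.exp(np.log(vals + pseudocount).mean(axis=1))
    else:
        if single:
            raise ValueError("meanz needs a cohort (DataFrame) of samples")
        z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=0)
        scores = z.mean(axis=1)
    scores = pd.Series(scores, index=frame.index, name=f"signature_{method}")
    scores.attrs["gene_set"] = tuple(present)
    scores.attrs["method"] = method
    return float(scores.iloc[0]) if single else scores
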