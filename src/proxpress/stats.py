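"""Shared statistical kernels: rank tests, multiplicity control, ROC/AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

__all__ = ["RankSumResult", "RocResult", "rank_sum_test", "bh_fdr", "roc_auc"]


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str  # "exact" or "normal"
    degenerate: bool = False  # all values identical across both samples


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def rank_sum_test(a, b, mode: str = "auto") -> RankSumResult:
    """Two-sided Mann-Whitney U test.

    In "auto" mode the p-value comes from exact enumeration when the smaller
    sample has at most 10 observations and there are no ties, and from the
    mid-rank normal approximation with continuity correction otherwise;
    "exact" and "normal" force the respective method. Identical values in
    both samples carry no ordering information: p = 1 by convention, flagged
    via ``degenerate``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    ties = _has_ties(a, b)
    if np.ptp(np.concatenate([a, b])) == 0:
        u = a.size * b.size / 2.0
        return RankSumResult(u, 1.0, "degenerate", degenerate=True)
    if mode == "exact" or (mode == "auto" and min(a.size, b.size) <= 10 and not ties):
        method = "exact"
    else:
        method = "normal"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)


def bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for a continuous score against binary labels.

    The AUC is the Mann-Whitney probability that a positive outscores a
    negative, ties counted half — computed from mid-ranks so tied scores are
    handled exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocResult(
        thresholds=thr, sensitivities=tpr, specificities=1.0 - fpr, auc=float(auc)
    )
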