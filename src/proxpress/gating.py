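"""Marker normalization and epithelial gating of cancer cells.

Cancer cells are labeled from epithelial markers (E-cadherin and/or
pan-cytokeratin). Positivity thresholds are fit per sample and per marker by
a two-component Gaussian mixture on log intensities, the threshold being the
intensity at which the two components' posterior probabilities are equal;
under the default "any" policy a cell is a cancer cell when positive for at
least one epithelial marker, under "all" it must be positive for every one.

Because mixture fitting operates on logs with a data-relative offset for
zeros, a global positive rescaling of a marker channel shifts the fit and
its threshold covariantly and leaves the labels unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .table import marker_columns

__all__ = ["NormalizationReport", "GatingResult", "normalize_markers", "gate_cancer_cells"]


@dataclass
class NormalizationReport:
    """Audit trail of a marker normalization: per (sample, marker) transform
    parameters and flags for markers that were constant within a sample."""

    mode: str
    params: pd.DataFrame  # sample_id, marker, mean, sd, constant
    flags: list[str] = field(default_factory=list)


@dataclass
class GatingResult:
    """Cancer-cell calls with the per-sample, per-marker thresholds used."""

    labels: pd.Series  # boolean, aligned with the gated table's index
    thresholds: pd.DataFrame  # sample_id, marker, threshold, method
    policy: str
    flags: list[str] = field(default_factory=list)


def normalize_markers(
    table: pd.DataFrame, mode: str = "zscore"
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Per-sample, per-marker log1p + z-scaling of intensities.

    "zscore" maps each marker within each sample to zero mean and unit
    variance on the log1p scale (population denominator); "raw" is the
    identity. A marker constant within a sample is centered but not scaled,
    and flagged in the report.
    """
    if mode not in ("zscore", "raw"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    markers = marker_columns(table)
    if mode == "raw":
        report = NormalizationReport(mode=mode, params=pd.DataFrame(
            columns=["sample_id", "marker", "mean", "sd", "constant"]))
        return table.copy(), report

    out = table.copy()
    rows = []
    flags = []
    for sample_id, idx in table.groupby("sample_id", sort=False).groups.items():
        for m in markers:
            v = np.log1p(table.loc[idx, m].to_numpy(dtype=float))
            mu = v.mean()
            sd = v.std(ddof=0)
            constant = sd < 1e-12
            if constant:
                flags.append(f"sample {sample_id}: marker {m} constant, not scaled")
                out.loc[idx, m] = v - mu
            else:
                out.loc[idx, m] = (v - mu) / sd
            rows.append(
                {"sample_id": sample_id, "marker": m, "mean": mu,
                 "sd": sd if not constant else np.nan, "constant": constant}
            )
    report = NormalizationReport(mode=mode, params=pd.DataFrame(rows), flags=flags)
    return out, report


def _log_transform(values: np.ndarray) -> np.ndarray | None:
    """Log with a data-relative offset for zeros; None if all zero."""
    positive = values[values > 0]
    if positive.size == 0:
        return None
    eps = 0.5 * positive.min()
    return np.log(np.where(values > 0, values, eps))


def _mixture_threshold(logv: np.ndarray, random_state: int) -> float | None:
    """Equal-posterior crossing of a 2-component GMM on log intensities.

    Components are seeded at the 25th/75th percentiles. Returns None when
    the fit is degenerate (collapsed components or no posterior crossing
    between the component means), signalling the percentile fallback.
    """
    q25, q75 = np.percentile(logv, [25, 75])
    gm = GaussianMixture(
        n_components=2,
        means_init=np.array([[q25], [q75]]),
        random_state=random_state,
        n_init=1,
    )
    gm.fit(logv.reshape(-1, 1))
    means = gm.means_.ravel()
    hi = int(np.argmax(means))
    lo = 1 - hi
    span = abs(means[hi] - means[lo])
    if span < 1e-6 * max(1.0, np.ptp(logv)) or gm.weights_.min() < 1e-3:
        return None

    def excess(x: float) -> float:
        return gm.predict_proba(np.array([[x]]))[0, hi] - 0.5

    a, b = means[lo], means[hi]
    if excess(a) >= 0 or excess(b) <= 0:
        return None
    return float(brentq(excess, a, b, xtol=1e-12))


def gate_cancer_cells(
    table: pd.DataFrame,
    epithelial_markers: tuple[str, ...] = ("ECAD", "PANCK"),
    policy: str = "any",
    random_state: int = 0,
) -> GatingResult:
    """Label cancer cells from epithelial-marker positivity.

    Positivity is intensity strictly above the fitted threshold, so a cell
    exactly at the equal-posterior point counts as non-cancer (the
    conservative choice for the pressure denominator). Degenerate mixture
    fits fall back to the sample's 75th-percentile intensity, flagged.
    """
    if policy not in ("any", "all"):
        raise ValueError(f"unknown gating policy {policy!r}")
    missing = [m for m in epithelial_markers if m not in table.columns]
    if missing:
        raise ValueError(f"epithelial markers absent from table: {missing}")

    positive = pd.DataFrame(False, index=table.index, columns=list(epithelial_markers))
    rows = []
    flags = []
    for sample_id, idx in table.groupby("sample_id", sort=False).groups.items():
        for m in epithelial_markers:
            raw = table.loc[idx, m].to_numpy(dtype=float)
            logv = _log_transform(raw)
            method = "gmm"
            log_thr = None
            if logv is not None:
                log_thr = _mixture_threshold(logv, random_state)
            if log_thr is None:
                method = "percentile75"
                flags.append(
                    f"sample {sample_id}: marker {m} degenerate mixture, "
                    "75th-percentile fallback"
                )
                thr = float(np.percentile(raw, 75))
            else:
                thr = float(np.exp(log_thr))
            positive.loc[idx, m] = raw > thr
            rows.append(
                {"sample_id": sample_id, "marker": m, "threshold": thr,
                 "method": method}
            )
    agg = positive.any(axis=1) if policy == "any" else positive.all(axis=1)
    return GatingResult(
        labels=agg,
        thresholds=pd.DataFrame(rows),
        policy=policy,
        flags=flags,
    )
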