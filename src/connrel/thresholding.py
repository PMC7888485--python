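"""Threshold sweeps: edge retention consistency and thresholded reliability.

Each subject-session connectome is thresholded independently, either by an
absolute r cutoff (values below t zeroed; the comparison is signed, so all
negative edges drop at any positive t) or by a relative/proportional rule
(the top ceil(p * E) edges by signed value retained, ties at the cut broken
by canonical edge order).

For every threshold the sweep reports, per edge, the "consistency ratio"
R_e: the number of subjects in which the edge survived thresholding in both
sessions, divided by the number in which it survived in at least one.
Edges never retained are excluded.  Reliability of consistently retained
edges is the ICC(3,1) computed only over the subjects retaining the edge in
both sessions (with a minimum-subject floor).

Trend statistics correlate the per-threshold medians against threshold
*stringency*: the r cutoff itself for absolute mode, the removed fraction
1 - p for relative mode.  Under this convention a consistency ratio that
falls as thresholding tightens appears as a negative Spearman rho in both
modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, EdgePanel, _check_aligned, vectorize_upper
from .reliability import BIN_SCHEMES, EdgewiseICC, bin_icc_array, icc_two_session

__all__ = [
    "ThresholdSweepReport",
    "default_threshold_grid",
    "threshold_absolute",
    "threshold_relative",
    "absolute_retention_mask",
    "relative_retention_mask",
    "consistency_ratio",
    "thresholded_icc",
    "threshold_sweep",
]


def default_threshold_grid() -> np.ndarray:
    """The 20 evenly spaced threshold values from 0.05 to 1.00."""
    return np.linspace(0.05, 1.0, 20)


def _validate_grid(thresholds: np.ndarray) -> np.ndarray:
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("threshold grid must be a 1-D array of >= 2 values")
    if np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if np.any((t <= 0) | (t > 1)):
        raise ValueError("thresholds must lie in (0, 1]")
    return t


def threshold_absolute(matrix: ConnectivityMatrix, t: float) -> ConnectivityMatrix:
    """Zero all off-diagonal entries with value < t; diagonal untouched."""
    if not 0 < t <= 1:
        raise ValueError("absolute threshold must lie in (0, 1]")
    values = matrix.values.copy()
    off = ~np.eye(values.shape[0], dtype=bool)
    drop = off & (values < t)
    values[drop] = 0.0
    return ConnectivityMatrix(
        values=values,
        region_names=list(matrix.region_names),
        subject_id=matrix.subject_id,
        session_id=matrix.session_id,
    )


def threshold_relative(matrix: ConnectivityMatrix, p: float) -> ConnectivityMatrix:
    """Retain the ceil(p * E) strongest edges by signed value, zero the rest."""
    if not 0 < p <= 1:
        raise ValueError("relative threshold must lie in (0, 1]")
    edges = vectorize_upper(matrix)
    mask = relative_retention_mask(edges[None, :], p)[0]
    new_edges = np.where(mask, edges, 0.0)
    r = matrix.n_regions
    values = matrix.values.copy()
    iu = np.triu_indices(r, k=1)
    values[iu] = new_edges
    values[(iu[1], iu[0])] = new_edges
    return ConnectivityMatrix(
        values=values,
        region_names=list(matrix.region_names),
        subject_id=matrix.subject_id,
        session_id=matrix.session_id,
    )


def absolute_retention_mask(values: np.ndarray, t: float) -> np.ndarray:
    """Boolean (subjects, edges) mask of edges surviving an absolute cutoff."""
    if not 0 < t <= 1:
        raise ValueError("absolute threshold must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    return np.isfinite(values) & (values >= t)


def relative_retention_mask(values: np.ndarray, p: float) -> np.ndarray:
    """Boolean (subjects, edges) mask of the per-row top ceil(p * E) edges.

    Ranking is by signed value; ties at the cut are broken by canonical
    edge order (lower index first).  NaN edges are never retained.
    """
    if not 0 < p <= 1:
        raise ValueError("relative threshold must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    n_sub, n_edges = values.shape
    k = ceil(p * n_edges)
    ranked = np.where(np.isfinite(values), values, -np.inf)
    # stable argsort of the negated values: equal values keep ascending
    # (canonical) edge order, so the tie at the cut resolves deterministically
    order = np.argsort(-ranked, axis=1, kind="stable")
    mask = np.zeros((n_sub, n_edges), dtype=bool)
    rows = np.arange(n_sub)[:, None]
    mask[rows, order[:, :k]] = True
    mask &= np.isfinite(values)
    return mask


def consistency_ratio(retained_s1: np.ndarray, retained_s2: np.ndarray) -> np.ndarray:
    """Per-edge ratio of both-session retention to any-session retention.

    Edges retained by no subject in either session get NaN (excluded from
    report summaries).
    """
    m1 = np.asarray(retained_s1, dtype=bool)
    m2 = np.asarray(retained_s2, dtype=bool)
    if m1.shape != m2.shape:
        raise ValueError("retention masks must have identical shape")
    both = (m1 & m2).sum(axis=0).astype(float)
    once = (m1 | m2).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(once > 0, both / once, np.nan)


def thresholded_icc(
    panel_s1: EdgePanel,
    panel_s2: EdgePanel,
    retained_s1: np.ndarray,
    retained_s2: np.ndarray,
    min_subjects: int = 10,
    alpha: float = 0.05,
) -> EdgewiseICC:
    """ICC(3,1) per edge over the subjects retaining it in both sessions."""
    _check_aligned(panel_s1, panel_s2)
    m1 = np.asarray(retained_s1, dtype=bool)
    m2 = np.asarray(retained_s2, dtype=bool)
    if m1.shape != panel_s1.values.shape or m2.shape != panel_s2.values.shape:
        raise ValueError("retention masks must align with the panels")
    return icc_two_session(
        panel_s1.values,
        panel_s2.values,
        valid=m1 & m2,
        alpha=alpha,
        min_subjects=min_subjects,
    )


@dataclass
class ThresholdSweepReport:
    """Per-threshold consistency and reliability summaries plus trends."""

    mode: str
    thresholds: np.ndarray
    min_subjects: int
    consistency_median: np.ndarray
    consistency_min: np.ndarray
    consistency_max: np.ndarray
    consistency_bins: list[dict[str, float]]
    n_reported_edges: np.ndarray
    icc_median: np.ndarray
    icc_bins: list[dict[str, float]]
    n_icc_edges: np.ndarray
    trend_consistency_rho: float
    trend_consistency_p: float
    trend_icc_rho: float
    trend_icc_p: float
    bin_scheme: str = "cicchetti4"
    extra: dict = field(default_factory=dict)

    def per_threshold_frame(self) -> pd.DataFrame:
        rows = {
            "threshold": self.thresholds,
            "n_reported_edges": self.n_reported_edges,
            "consistency_median": self.consistency_median,
            "consistency_min": self.consistency_min,
            "consistency_max": self.consistency_max,
            "icc_median": self.icc_median,
            "n_icc_edges": self.n_icc_edges,
        }
        df = pd.DataFrame(rows)
        for label, _ in BIN_SCHEMES[self.bin_scheme]:
            df[f"consistency_{label}"] = [b[label] for b in self.consistency_bins]
            df[f"icc_{label}"] = [b[label] for b in self.icc_bins]
        return df

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "bin_scheme": self.bin_scheme,
            "min_subjects": self.min_subjects,
            "thresholds": self.thresholds.tolist(),
            "consistency_median": self.consistency_median.tolist(),
            "consistency_min": self.consistency_min.tolist(),
            "consistency_max": self.consistency_max.tolist(),
            "consistency_bins": self.consistency_bins,
            "n_reported_edges": self.n_reported_edges.tolist(),
            "icc_median": self.icc_median.tolist(),
            "icc_bins": self.icc_bins,
            "n_icc_edges": self.n_icc_edges.tolist(),
            "trend": {
                "consistency_rho": self.trend_consistency_rho,
                "consistency_p": self.trend_consistency_p,
                "icc_rho": self.trend_icc_rho,
                "icc_p": self.trend_icc_p,
            },
        }


def _bin_proportions(values: np.ndarray, scheme: str) -> dict[str, float]:
    ok = np.isfinite(values)
    labels = bin_icc_array(values[ok], scheme)
    total = max(int(ok.sum()), 1)
    return {
        label: float((labels == label).sum()) / total
        for label, _ in BIN_SCHEMES[scheme]
    }


def _nan_stat(values: np.ndarray, fn) -> float:
    ok = np.isfinite(values)
    return float(fn(values[ok])) if ok.any() else float("nan")


def threshold_sweep(
    panel_s1: EdgePanel,
    panel_s2: EdgePanel,
    mode: str = "relative",
    thresholds: np.ndarray | None = None,
    min_subjects: int = 10,
    alpha: float = 0.05,
    bin_scheme: str = "cicchetti4",
) -> ThresholdSweepReport:
    """Run the full threshold sweep over a session pair of edge panels."""
    if mode not in ("absolute", "relative"):
        raise ValueError("mode must be 'absolute' or 'relative'")
    _check_aligned(panel_s1, panel_s2)
    if panel_s1.n_subjects == 0:
        raise ValueError("empty cohort")
    grid = _validate_grid(
        default_threshold_grid() if thresholds is None else thresholds
    )
    mask_fn = absolute_retention_mask if mode == "absolute" else relative_retention_mask

    cons_med, cons_min, cons_max = [], [], []
    cons_bins, icc_bins = [], []
    icc_med, n_rep, n_icc = [], [], []
    for t in grid:
        m1 = mask_fn(panel_s1.values, t)
        m2 = mask_fn(panel_s2.values, t)
        ratios = consistency_ratio(m1, m2)
        cons_med.append(_nan_stat(ratios, np.median))
        cons_min.append(_nan_stat(ratios, np.min))
        cons_max.append(_nan_stat(ratios, np.max))
        cons_bins.append(_bin_proportions(ratios, bin_scheme))
        n_rep.append(int(np.isfinite(ratios).sum()))
        res = thresholded_icc(panel_s1, panel_s2, m1, m2, min_subjects, alpha)
        icc_med.append(_nan_stat(res.icc, np.median))
        icc_bins.append(_bin_proportions(res.icc, bin_scheme))
        n_icc.append(int(np.isfinite(res.icc).sum()))

    stringency = grid if mode == "absolute" else 1.0 - grid
    rho_c, p_c = _trend(stringency, np.asarray(cons_med))
    rho_i, p_i = _trend(stringency, np.asarray(icc_med))

    return ThresholdSweepReport(
        mode=mode,
        thresholds=grid,
        min_subjects=min_subjects,
        consistency_median=np.asarray(cons_med),
        consistency_min=np.asarray(cons_min),
        consistency_max=np.asarray(cons_max),
        consistency_bins=cons_bins,
        n_reported_edges=np.asarray(n_rep),
        icc_median=np.asarray(icc_med),
        icc_bins=icc_bins,
        n_icc_edges=np.asarray(n_icc),
        trend_consistency_rho=rho_c,
        trend_consistency_p=p_c,
        trend_icc_rho=rho_i,
        trend_icc_p=p_i,
        bin_scheme=bin_scheme,
    )


def _trend(stringency: np.ndarray, medians: np.ndarray) -> tuple[float, float]:
    from .inference import spearman

    ok = np.isfinite(medians)
    if ok.sum() < 3 or np.unique(medians[ok]).size < 2:
        return float("nan"), float("nan")
    res = spearman(stringency[ok], medians[ok])
    return res.statistic, res.p_value
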