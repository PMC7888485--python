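"""Consistency intraclass correlation ICC(3,1) with F-based intervals.

The statistic is the consistency ICC from a two-way mixed model with fixed
session effects — ICC "C-1" in McGraw & Wong, ICC(3,1) in Shrout & Fleiss:

    ICC = (BMS - EMS) / (BMS + (k - 1) EMS)

where BMS is the between-subject mean square and EMS the residual mean
square of a two-way ANOVA without interaction (subject and session
effects removed).  Confidence bounds come from the F distribution:

    FL = (BMS/EMS) / F_{1-a/2; n-1, (n-1)(k-1)}
    FU = (BMS/EMS) * F_{1-a/2; (n-1)(k-1), n-1}
    CI = ((FL - 1)/(FL + k - 1), (FU - 1)/(FU + k - 1))

Negative ICC estimates are retained unclamped.  Edge panels are handled by
a vectorized two-session implementation that agrees with the scalar ANOVA
to double precision; subject subsets (for thresholded reliability) are
supported through per-edge validity masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "ICCResult",
    "EdgewiseICC",
    "BIN_SCHEMES",
    "icc_c1",
    "icc_two_session",
    "edgewise_icc",
    "bin_icc",
    "bin_icc_array",
    "summarize_icc",
]

#: reliability bin schemes: ordered (label, upper cutoff) pairs; intervals
#: are closed on the left at each lower cutoff (0.40 -> "fair" under
#: cicchetti4, 0.80 -> "perfect" under xingzuo5)
BIN_SCHEMES: dict[str, list[tuple[str, float]]] = {
    "cicchetti4": [
        ("poor", 0.40),
        ("fair", 0.60),
        ("good", 0.75),
        ("excellent", np.inf),
    ],
    "xingzuo5": [
        ("slight", 0.20),
        ("fair", 0.40),
        ("moderate", 0.60),
        ("substantial", 0.80),
        ("perfect", np.inf),
    ],
}


def bin_icc(value: float, scheme: str = "cicchetti4") -> str | None:
    """Reliability bin label for one ICC value; None for non-finite input."""
    if scheme not in BIN_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {list(BIN_SCHEMES)}")
    if not np.isfinite(value):
        return None
    for label, upper in BIN_SCHEMES[scheme]:
        if value < upper:
            return label
    return BIN_SCHEMES[scheme][-1][0]


def bin_icc_array(values: np.ndarray, scheme: str = "cicchetti4") -> np.ndarray:
    """Vectorized binning; non-finite entries map to None."""
    values = np.asarray(values, dtype=float)
    labels = [label for label, _ in BIN_SCHEMES[scheme]]
    cutoffs = [upper for _, upper in BIN_SCHEMES[scheme][:-1]]
    idx = np.searchsorted(cutoffs, values, side="right")
    out = np.array([labels[i] for i in idx.ravel()], dtype=object).reshape(values.shape)
    out[~np.isfinite(values)] = None
    return out


@dataclass
class ICCResult:
    """Scalar ICC(3,1) estimate with F statistic and confidence bounds."""

    icc: float
    f_stat: float
    ci_lower: float
    ci_upper: float
    n: int
    k: int
    alpha: float = 0.05

    @property
    def bin4(self) -> str | None:
        return bin_icc(self.icc, "cicchetti4")

    @property
    def bin5(self) -> str | None:
        return bin_icc(self.icc, "xingzuo5")


def _ci_from_f(f: np.ndarray, df1: np.ndarray, df2: np.ndarray, k: int,
               alpha: float) -> tuple[np.ndarray, np.ndarray]:
    q = 1.0 - alpha / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fl = f / _stats.f.ppf(q, df1, df2)
        fu = f * _stats.f.ppf(q, df2, df1)
        lower = (fl - 1.0) / (fl + k - 1.0)
        upper = (fu - 1.0) / (fu + k - 1.0)
    lower = np.where(np.isinf(fl), 1.0, lower)
    upper = np.where(np.isinf(fu), 1.0, upper)
    return lower, upper


def icc_c1(x: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(3,1) of an n x k measurement table (subjects x sessions).

    Requires n >= 3 complete rows and k >= 2 columns.  All-identical data
    (zero BMS and EMS) yield NaN, reported as missing.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("input must be a 2-D subjects x sessions table")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 measurements per subject, got {k}")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not allowed; drop subjects first")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))

    if bms + (k - 1) * ems == 0.0:
        return ICCResult(np.nan, np.nan, np.nan, np.nan, n, k, alpha)
    icc = (bms - ems) / (bms + (k - 1) * ems)
    with np.errstate(divide="ignore"):
        f = bms / ems if ems > 0 else np.inf
    lower, upper = _ci_from_f(
        np.asarray(f), np.asarray(n - 1), np.asarray((n - 1) * (k - 1)), k, alpha
    )
    return ICCResult(float(icc), float(f), float(lower), float(upper), n, k, alpha)


@dataclass
class EdgewiseICC:
    """Vectorized per-feature ICC(3,1) results (k = 2 sessions).

    Missing features (too few subjects, or degenerate all-identical data)
    carry NaN entries and are excluded from summaries.
    """

    icc: np.ndarray
    f_stat: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: np.ndarray
    k: int = 2
    alpha: float = 0.05
    feature_names: list[str] = field(default_factory=list)

    def bins(self, scheme: str = "cicchetti4") -> np.ndarray:
        return bin_icc_array(self.icc, scheme)

    def summary(self) -> dict:
        return summarize_icc(self)


def icc_two_session(
    x1: np.ndarray,
    x2: np.ndarray,
    valid: np.ndarray | None = None,
    alpha: float = 0.05,
    min_subjects: int = 3,
) -> EdgewiseICC:
    """Columnwise ICC(3,1) of two aligned subjects x features tables.

    ``valid`` masks, per feature, the subjects entering that feature's
    ANOVA (k = 2 stays balanced within the retained subjects).  Features
    with fewer than ``min_subjects`` valid subjects are NaN.

    For k = 2 the mean squares reduce to sums and differences:
    with s_i = x1_i + x2_i and d_i = x1_i - x2_i over the n valid subjects,
    BMS = sum((s - s_mean)^2) / (2 (n-1)) and
    EMS = sum((d - d_mean)^2) / (2 (n-1)).
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape != x2.shape:
        raise ValueError("session tables must have identical shape")
    finite = np.isfinite(x1) & np.isfinite(x2)
    if valid is None:
        valid = finite
    else:
        valid = np.asarray(valid, dtype=bool) & finite
    min_subjects = max(int(min_subjects), 3)

    w = valid.astype(float)
    n = w.sum(axis=0)
    enough = n >= min_subjects
    n_safe = np.where(n > 1, n, 2.0)

    s = np.where(valid, x1 + x2, 0.0)
    d = np.where(valid, x1 - x2, 0.0)
    s_mean = s.sum(axis=0) / n_safe
    d_mean = d.sum(axis=0) / n_safe
    ss_s = (np.where(valid, (s - s_mean) ** 2, 0.0)).sum(axis=0)
    ss_d = (np.where(valid, (d - d_mean) ** 2, 0.0)).sum(axis=0)
    denom = 2.0 * (n_safe - 1.0)
    bms = ss_s / denom
    ems = ss_d / denom

    total = bms + ems  # k = 2
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(total > 0, (bms - ems) / total, np.nan)
        f = np.where(ems > 0, bms / ems, np.inf)
    f = np.where(bms + ems > 0, f, np.nan)
    icc = np.where(enough, icc, np.nan)
    f = np.where(enough, f, np.nan)

    df = n_safe - 1.0  # df1 = n-1, df2 = (n-1)(k-1) = n-1 for k = 2
    lower, upper = _ci_from_f(f, df, df, 2, alpha)
    bad = ~np.isfinite(icc)
    lower = np.where(bad, np.nan, lower)
    upper = np.where(bad, np.nan, upper)
    return EdgewiseICC(
        icc=icc,
        f_stat=f,
        ci_lower=lower,
        ci_upper=upper,
        n=n.astype(int),
        k=2,
        alpha=alpha,
    )


def edgewise_icc(panel_s1, panel_s2, alpha: float = 0.05) -> EdgewiseICC:
    """Per-edge ICC(3,1) across two aligned session edge panels."""
    from .connectome import _check_aligned

    _check_aligned(panel_s1, panel_s2)
    res = icc_two_session(panel_s1.values, panel_s2.values, alpha=alpha)
    res.feature_names = [f"{i}_{j}" for i, j in panel_s1.edge_index]
    return res


def summarize_icc(results: EdgewiseICC | np.ndarray,
                  ci_lower: np.ndarray | None = None,
                  ci_upper: np.ndarray | None = None) -> dict:
    """Median/min/max ICC, bin proportions (both schemes), CI-width median."""
    if isinstance(results, EdgewiseICC):
        icc = results.icc
        ci_lower = results.ci_lower
        ci_upper = results.ci_upper
    else:
        icc = np.asarray(results, dtype=float)
    ok = np.isfinite(icc)
    if not ok.any():
        raise ValueError("no non-missing ICC values to summarize")
    vals = icc[ok]
    out: dict = {
        "n_features": int(icc.size),
        "n_missing": int(icc.size - vals.size),
        "median": float(np.median(vals)),
        "min": float(vals.min()),
        "max": float(vals.max()),
    }
    for scheme in BIN_SCHEMES:
        labels = bin_icc_array(vals, scheme)
        out[f"bin_proportions_{scheme}"] = {
            label: float((labels == label).mean())
            for label, _ in BIN_SCHEMES[scheme]
        }
    if ci_lower is not None and ci_upper is not None:
        widths = np.asarray(ci_upper, dtype=float) - np.asarray(ci_lower, dtype=float)
        widths = widths[np.isfinite(widths)]
        out["ci_width_median"] = float(np.median(widths)) if widths.size else None
    return out
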