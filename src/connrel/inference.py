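"""Rank-based comparison tests and the reliability sample-size utility.

Three nonparametric tests cover the study-level contrasts: Kruskal-Wallis
(reliability across parcellations), Wilcoxon signed rank (paired GSR+ vs
GSR- reliability), and Spearman correlation (edge strength vs reliability;
threshold trends).  ``icc_sample_size`` implements the Walter-Eliasziw-
Donner approximation for the minimum number of subjects needed to detect a
given ICC.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log

import numpy as np
from scipy import stats as _stats

__all__ = [
    "TestOutcome",
    "kruskal_wallis",
    "wilcoxon_signed_rank",
    "spearman",
    "icc_sample_size",
]


@dataclass
class TestOutcome:
    """Test statistic (H, Z or rho), two-sided p-value and sample size(s)."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    name: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": list(self.n),
        }


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x[np.isfinite(x)]


def kruskal_wallis(groups) -> TestOutcome:
    """Kruskal-Wallis H test (tie-corrected, chi-square p) across groups.

    All-identical data across every group yield H = 0, p = 1.
    """
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 1 for g in cleaned):
        raise ValueError("every group needs at least one value")
    if sum(g.size for g in cleaned) < 3:
        raise ValueError("need at least 3 values in total")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return TestOutcome(0.0, 1.0, tuple(g.size for g in cleaned),
                           "kruskal_wallis")
    h, p = _stats.kruskal(*cleaned)
    return TestOutcome(float(h), float(p), tuple(g.size for g in cleaned),
                       "kruskal_wallis")


def wilcoxon_signed_rank(x, y) -> TestOutcome:
    """Wilcoxon signed-rank test on paired samples, normal approximation.

    Tests the differences ``y - x``; zero differences are dropped; the
    reported Z is continuity-corrected and positive when y tends to exceed
    x.  Raises if every difference is zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    d = y - x
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    res = _stats.wilcoxon(
        y, x, zero_method="wilcox", correction=True, alternative="two-sided",
        method="approx",
    )
    # scipy's two-sided zstatistic derives from the smaller rank sum and so
    # carries no direction; recover the sign from the signed rank sums
    ranks = _stats.rankdata(np.abs(d))
    signed_sum = float(np.sum(np.sign(d) * ranks))
    z = float(np.copysign(abs(res.zstatistic), signed_sum)) if signed_sum else 0.0
    return TestOutcome(z, float(res.pvalue), (int(d.size),),
                       "wilcoxon_signed_rank")


def spearman(x, y) -> TestOutcome:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance in ranks")
    rho, p = _stats.spearmanr(x, y)
    return TestOutcome(float(rho), float(p), (int(x.size),), "spearman")


def icc_sample_size(
    rho1: float,
    rho0: float = 0.0,
    k: int = 2,
    alpha: float = 0.05,
    power: float = 0.80,
) -> int:
    """Minimum subjects to detect ICC >= rho1 against rho0, k measurements.

    Walter-Eliasziw-Donner approximation with one-sided alpha: with
    theta(rho) = (1 + (k-1) rho) / (1 - rho) and C0 = theta(rho0)/theta(rho1),

        n = 1 + 2 k (z_{1-alpha} + z_{1-beta})^2 / ((k-1) (ln C0)^2)

    rounded up to the next integer.
    """
    if not 0.0 <= rho0 < 1.0 or not 0.0 < rho1 < 1.0:
        raise ValueError("ICC values must lie in [0, 1)")
    if rho1 <= rho0:
        raise ValueError("rho1 must exceed rho0; no finite sample size otherwise")
    if k < 2:
        raise ValueError("need at least 2 measurements per subject")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")

    def theta(rho: float) -> float:
        return (1.0 + (k - 1) * rho) / (1.0 - rho)

    c0 = theta(rho0) / theta(rho1)
    z = _stats.norm.ppf(1.0 - alpha) + _stats.norm.ppf(power)
    n = 1.0 + 2.0 * k * z**2 / ((k - 1) * log(c0) ** 2)
    return int(ceil(n))
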