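"""Per-run timeseries conditioning for connectome construction.

The processing chain applied to each resting-state run is, in order:
optional global signal regression (GSR), zero-phase high-pass filtering,
motion scrubbing by framewise relative RMS displacement, and within-session
run concatenation.  Subjects whose flagged-frame fraction exceeds a limit in
any run are excluded upstream (see :func:`subject_passes_motion`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal

__all__ = [
    "ParcellatedRun",
    "SessionTimeseries",
    "regress_global_signal",
    "highpass_filter",
    "scrub",
    "subject_passes_motion",
    "concatenate_session",
    "preprocess_session",
]


@dataclass
class ParcellatedRun:
    """One run's parcellated signal plus its motion trace.

    Attributes
    ----------
    signal : ndarray, shape (timepoints, regions)
        Mean timeseries of each region.
    rms : ndarray, shape (timepoints,)
        Framewise relative root-mean-square displacement in mm
        (first frame conventionally 0).
    tr_seconds : float
        Sampling interval.
    region_names : list of str
        Column labels, one per region.
    """

    signal: np.ndarray
    rms: np.ndarray
    tr_seconds: float
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.rms = np.asarray(self.rms, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D timepoints x regions array")
        if self.rms.shape != (self.signal.shape[0],):
            raise ValueError(
                f"rms length {self.rms.shape} does not match "
                f"{self.signal.shape[0]} timepoints"
            )
        if np.any(self.rms < 0):
            raise ValueError("rms values must be non-negative")
        if not self.region_names:
            self.region_names = [f"R{i:03d}" for i in range(self.signal.shape[1])]
        if len(self.region_names) != self.signal.shape[1]:
            raise ValueError("region_names length must equal number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[0]

    @property
    def n_regions(self) -> int:
        return self.signal.shape[1]


@dataclass
class SessionTimeseries:
    """Concatenated, conditioned timeseries for one subject-session."""

    signal: np.ndarray
    kept_frame_count: int
    flagged_fraction_per_run: list[float]
    region_names: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.kept_frame_count != self.signal.shape[0]:
            raise ValueError("kept_frame_count must equal row count of signal")


def regress_global_signal(run: ParcellatedRun) -> ParcellatedRun:
    """Regress the cross-region mean timeseries out of every region.

    Each region's series is replaced by the residuals of its least-squares
    fit on an intercept plus the mean series, so residuals are orthogonal to
    both.  Applied to the raw run, before any filtering.
    """
    x = run.signal
    if x.shape[0] < 2:
        raise ValueError("global signal regression needs at least 2 timepoints")
    if x.shape[1] < 1:
        raise ValueError("global signal regression needs at least 1 region")
    g = x.mean(axis=1)
    gc = g - g.mean()
    denom = gc @ gc
    if denom <= 1e-15 * x.shape[0]:
        warnings.warn(
            "global mean series has zero variance; intercept-only residuals",
            RuntimeWarning,
            stacklevel=2,
        )
        resid = x - x.mean(axis=0, keepdims=True)
    else:
        xc = x - x.mean(axis=0, keepdims=True)
        beta = (gc @ xc) / denom
        resid = xc - np.outer(gc, beta)
    return replace(run, signal=resid)


def highpass_filter(run: ParcellatedRun, cutoff_hz: float = 0.008) -> ParcellatedRun:
    """Zero-phase 4th-order Butterworth high-pass of every region's series.

    The filter is applied forward-backward (``sosfiltfilt``), preserving
    timing.  Residual column means are subtracted afterwards so the output is
    exactly mean-free, as a high-pass stage should be.
    """
    fs = 1.0 / run.tr_seconds
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs / 2:.4g}) Hz"
        )
    sos = _signal.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if run.n_timepoints <= padlen:
        raise ValueError(
            f"run has {run.n_timepoints} timepoints; zero-phase filtering "
            f"requires more than {padlen}"
        )
    filtered = _signal.sosfiltfilt(sos, run.signal, axis=0)
    filtered = filtered - filtered.mean(axis=0, keepdims=True)
    return replace(run, signal=filtered)


def scrub(
    run: ParcellatedRun, rms_threshold: float = 0.30
) -> tuple[ParcellatedRun, float]:
    """Delete frames whose RMS displacement strictly exceeds the threshold.

    Returns the scrubbed run and the flagged fraction.  Frames exactly at
    the threshold are kept (strict inequality).  Remaining frames preserve
    their original order.
    """
    flagged = run.rms > rms_threshold
    flagged_fraction = float(flagged.mean())
    if flagged.all():
        raise ValueError(
            f"all {run.n_timepoints} frames exceed RMS {rms_threshold}; "
            "nothing left after scrubbing"
        )
    keep = ~flagged
    out = replace(run, signal=run.signal[keep], rms=run.rms[keep])
    return out, flagged_fraction


def subject_passes_motion(
    flagged_fractions: Sequence[float], max_fraction: float = 0.15
) -> bool:
    """False iff any run's flagged-frame fraction strictly exceeds the limit."""
    fractions = list(flagged_fractions)
    if not fractions:
        raise ValueError("at least one run is required")
    return not any(f > max_fraction for f in fractions)


def concatenate_session(runs: Sequence[ParcellatedRun],
                        flagged_fractions: Sequence[float] | None = None
                        ) -> SessionTimeseries:
    """Demean each run's columns, then stack rows in the given run order.

    Per-run demeaning prevents baseline offsets between runs from inflating
    pooled correlations.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("at least one run is required")
    names = runs[0].region_names
    for r in runs[1:]:
        if r.region_names != names:
            raise ValueError("runs must share an identical region order")
    blocks = [r.signal - r.signal.mean(axis=0, keepdims=True) for r in runs]
    stacked = np.vstack(blocks)
    if flagged_fractions is None:
        flagged_fractions = [float("nan")] * len(runs)
    return SessionTimeseries(
        signal=stacked,
        kept_frame_count=stacked.shape[0],
        flagged_fraction_per_run=[float(f) for f in flagged_fractions],
        region_names=list(names),
        tr_seconds=runs[0].tr_seconds,
    )


def preprocess_session(
    runs: Sequence[ParcellatedRun],
    gsr: bool = False,
    hp_cutoff_hz: float = 0.008,
    rms_threshold: float = 0.30,
) -> SessionTimeseries:
    """Condition and concatenate one session's runs.

    Order is fixed: GSR (if enabled) -> high-pass -> scrub -> concatenate.
    """
    processed: list[ParcellatedRun] = []
    fractions: list[float] = []
    for run in runs:
        r = regress_global_signal(run) if gsr else run
        r = highpass_filter(r, hp_cutoff_hz)
        r, frac = scrub(r, rms_threshold)
        processed.append(r)
        fractions.append(frac)
    return concatenate_session(processed, fractions)
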